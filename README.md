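# mprikit

Semi-quantitative analysis of first-pass myocardial stress-perfusion MRI:
AHA 16-segment time–signal-intensity (TSI) curves, maximum upslope, relative
upslope, the myocardial perfusion reserve index (MPRI), rule-based
perfusion-defect classification, and the reproducibility statistics used to
validate such measurements — together with a synthetic perfusion phantom
whose ground truth is known in closed form.

## The problem

First-pass perfusion MRI images the initial transit of a gadolinium bolus
through the left ventricle at three short-axis levels (base, mid, apex).
Hypoperfused myocardium enhances more slowly than normal myocardium, so the
steepness of each region's enhancement carries flow information. The
standard semi-quantitative chain is:

- **TSI curves**: mean signal intensity over time for each AHA segment
  (6 basal, 6 mid, 4 apical, referenced to the anterior RV insertion) and
  for a blood-pool ROI in the LV cavity;
- **maximum upslope**: the steepest rate of signal rise (au/s) of a TSI
  curve during bolus wash-in, estimated here as the largest
  ordinary-least-squares slope over a sliding k-frame window (default
  k = 3) between first enhancement and the curve's peak;
- **relative upslope** = segment upslope / blood-pool upslope, which
  normalizes for bolus shape and injection differences;
- **MPRI** = relative upslope at stress / relative upslope at rest, per
  segment; the **global MPRI** is the mean over segments. MPRI is a proxy
  for perfusion reserve: segments that cannot augment flow under a
  vasodilator stressor have low MPRI;
- **defect rules**: a visual deficit present at stress but not rest is an
  inducible (reversible) defect; present at both states it is scar
  (*fixed*) if late gadolinium enhancement (LGE) marks the same territory,
  otherwise an artifact.

Patient images for such studies are not generally available, so `mprikit`
ships a phantom generator: a gamma-variate bolus fills the LV lumen and
each segment enhances as a pure-uptake compartment with its own flow scalar
F, making the true MPRI of every segment exactly `F_stress / F_rest`. Every
stage — rigid motion correction, segmentation, curve extraction, upslope,
MPRI, defect calling, Bland–Altman/ICC statistics — is validated against
that closed-form truth.

## Worked example

Simulate a phantom (flow doubles uniformly from rest to stress, 1 au
Gaussian noise) and quantify it end to end:

```
$ mprikit run --out demo --seed 1
global MPRI 1.9780 (phantom truth 2.0000); results in demo/results

$ mprikit quantify --rest demo/phantom/rest.nii.gz \
    --stress demo/phantom/stress.nii.gz \
    --contours demo/phantom/contours --out demo/res2 --k 3
global MPRI: 1.9780 over 16 segments
  basal MPRI: 1.9841
  mid MPRI: 1.9605
  apical MPRI: 1.9951
```

The recovered global MPRI (1.978) sits within ~1% of the phantom's true
perfusion reserve (2.0); the residual error is the 1 au image noise
propagating through the upslope estimator. `demo/res2/segments.csv` lists
per-segment relative upslopes, MPRI, deficit flags and classifications;
`mpri.json` and `defects.json` hold the aggregates and rule-based calls.

The numbered scripts under `analysis/` rerun the package's study-level
experiments (phantom generation, MPRI recovery, an inducible-defect study,
motion robustness, test-retest reproducibility) and write their tables
under `results/`.

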