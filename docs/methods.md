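# Methods

## Phantom model

The generator emulates a dual-state (rest/stress) first-pass acquisition at
three short-axis levels. Each slice is an annulus (endocardial and
epicardial circles, the apical pair scaled by 0.7 because the apex is
smaller; the scale is configurable and carries no anatomical claim) on a
48×48 grid at 2.8 mm in-plane resolution — the pixel size typical of
clinical first-pass imaging — with 60 frames at dt = 1 s and 5 pre-bolus
baseline frames. Clinical reports rarely state frame rate or dynamic
count, so these defaults are explicit configuration, not claims about any
particular protocol.

**Arterial input.** The LV lumen follows an amplitude-normalized
gamma-variate bolus

    S_blood(t) = S0 + A · ((t−t0)/(αβ))^α · exp(α − (t−t0)/β),   t > t0,

chosen because its peak is analytically `S0 + A` at `t = t0 + αβ`, giving
closed-form anchors for tests. Defaults: S0 = 20 au, t0 = 8 s, α = 3,
β = 4 s, A = 80 au at rest and 100 au at stress (hyperemia increases
cardiac output and bolus compactness; only the amplitude differs between
states so that the relative-upslope normalization cancels it exactly).

**Tissue model.** Each segment enhances as a pure-uptake compartment,

    S_myo(t_n) = S0_myo + F · dt · Σ_{i≤n} (S_blood(t_i) − S0),

with no washout during the simulated window. First-pass upslope indices
are insensitive to washout, and the choice makes the maximum instantaneous
slope equal `F · max(S_blood − S0)`: relative upslope is proportional to F
and the true MPRI of every segment is exactly `F_stress / F_rest`
(default F = 0.05 rest, 0.10 stress → true MPRI 2.0). Deficits are
expressed purely through flows: a reduced `F_stress` alone is a reversible
defect; reduction in both states is a fixed one.

**Noise and motion.** Noise is additive Gaussian (not Rician): in the
enhancement regime SNR is high and the Gaussian approximation is standard;
this is a documented simplification, not a claim about magnitude images
near zero signal. Motion is an integer in-plane random walk (steps in
{−1,0,1}² per frame, clipped to ±amplitude, starting at zero), applied
identically to both states and to all slices of a frame. Integer
translation is exactly recoverable, which turns motion correction into a
testable contract rather than a best-effort heuristic. Through-plane
motion, rotation, deformation and gating artifacts are out of scope, so
passing tests bound algorithmic correctness, not performance on real
breathing patterns. An optional dark-rim flag darkens the one-pixel
subendocardial ring to 80% of its tissue signal while the bolus is in
transit in both states, reproducing the phenotype of the classic artifact;
detecting it is a human/qualitative task and is not attempted.

## Segmentation and geometry

Pixel membership uses a frozen convention: 0-based indices, pixel centers
at integer (x, y), x right / y down. A pixel is myocardium iff its center
is on-or-inside the epicardial polygon, not on-or-inside the endocardial
polygon, and outside every papillary-exclusion polygon (even-odd rule;
papillary muscles are excluded from segmental signal as in manual
clinical contouring). Segment sectors are equal angles about the
endocardial centroid with angle zero toward the RV-insertion landmark and
increasing `atan2(y−cy, x−cx)`; basal/mid slices get six 60° sectors
(labels 1–6 / 7–12 in bull's-eye order), apical slices four 90° sectors
(13–16). Vendor software does not publish its angular convention; any
consistent choice yields identical MPRI statistics, so this one is frozen
for reproducibility. Exact sector-boundary ties go to the lower-numbered
segment; a tie for the curve's global peak takes the latest index so that
plateaus still admit slope windows. The blood-pool ROI is the endocardial
polygon eroded by 2 px (default slice: mid) to avoid partial-volume border
pixels. Whether clinical packages erode contours before TSI extraction is
unknown; the default here is no myocardial erosion.

LV volumes use summation of discs over endocardial areas
(`volume = Σ area · (thickness + gap)`), end diastole/systole selected as
the max/min phase volume (no ECG in scope), and BSA by Mosteller
(`√(height·weight/3600)`) — the most widely used formula where none is
otherwise specified.

## Upslope, MPRI and defect rules

Baseline is the mean of the first `n_baseline` frames; enhancement starts
at the first frame exceeding baseline + 3·SD of those frames, with an
absolute 1 au tolerance when the baseline SD is zero (noise-free curves).
Because of that absolute fallback, enhancement detection on *noise-free*
data is not invariant under extreme rescaling; with any measurable noise
the 3·SD rule applies and the whole chain is scale-invariant to machine
precision (asserted in tests). The gamma-variate rises smoothly, so the
detected enhancement index lags the true onset by 1–2 frames — the time
the curve needs to clear the tolerance — which is why tests assert the
closed-form crossing rather than the onset frame itself.

Maximum upslope fits OLS on every contiguous k-frame window starting at or
after enhancement and ending at or before (peak + 1), excluding
recirculation; ties take the earliest window. k defaults to 3 frames —
small enough to track fast pediatric bolus dynamics, configurable because
vendor estimators do not document their window. Slopes are per second
using frame times from the NIfTI time zoom. No baseline subtraction is
applied (OLS slopes are shift-invariant); baseline estimation only anchors
the search range. A segment with non-positive rest relative upslope raises
an error naming the segment rather than emitting an infinite MPRI.

The defect decision table over (stress deficit, rest deficit, LGE) is:
stress∧rest∧¬LGE → artifact; stress∧rest∧LGE → fixed; stress∧¬rest →
reversible; neither → normal. The rest-only cell is not covered by the
clinical rules this table encodes; it is mapped to *artifact* (a rest-only
"deficit" cannot be inducible ischemia) and surfaced as such — an
extrapolation, flagged here deliberately. Visual deficit calls are
replaced by an automated surrogate for phantom work: a segment is flagged
when its within-state relative upslope falls below 0.75× the median of
that state's segments.

Registration maximizes Pearson correlation between each frame and a
reference frame (default: frame 0, which the phantom's random walk leaves
unshifted) over integer shifts in a ±5 px window, ties to the smallest
shift magnitude then lexicographic. With zero-filled borders and noise-free
phantoms the correlation is exactly 1 at the true shift, so recovery is
exact by construction; under 1 au noise it remains exact in ≥95% of
frames.

## Statistics

- **Welch t-test** from group summaries (means/SDs/ns; raw samples are
  reduced to summaries first), two-sided, Welch–Satterthwaite df; Welch is
  the safer default when variances may differ.
- **Wilcoxon rank-sum** with midrank ties: exact two-sided p by full
  enumeration of rank-sum assignments for total n ≤ 20,
  `p = min(1, 2·min(P(W≤w), P(W≥w)))`; tie-corrected normal approximation
  above that.
- **Bland–Altman**: bias = mean(x−y), limits of agreement bias ± 1.96·SD
  (sample SD, n−1), and COV = 100·(SD(d)/√2)/grand mean — the
  within-subject-SD convention, stated explicitly because published COVs
  rarely give their formula.
- **ICC(2,1)**: two-way random effects, absolute agreement, single
  measurement, from the subjects×raters ANOVA mean squares, with the
  standard F-based 95% CI (Satterthwaite denominator df). Zero
  between-subject variance degenerates to ICC = 0 with a warning. All
  tests are two-sided.

## Problem sizes and numerical choices

The validation experiments use the phantom at its default size (three
48×48 slices, 60 frames), 20 replicate seeds per condition for stochastic
claims, 200 random curves for the upslope-oracle sweep, and 500 simulated
subjects for ICC recovery — sizes at which every stochastic quantity is
stable to well within its asserted tolerance while the whole suite runs in
well under a minute. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; repeated runs are byte-identical.

## Known limitations

Gaussian noise, integer-translation-only motion, no washout, no
T1-weighting/saturation physics, circular phantom anatomy, and an
automated deficit surrogate in place of expert visual reads. Passing the
phantom suite therefore demonstrates correctness of the computational
chain under its stated model, not clinical performance on patient images.
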