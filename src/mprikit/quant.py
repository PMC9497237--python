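"""Semi-quantitative perfusion analysis: registration, TSI curves, upslope, MPRI.

The analysis chain mirrors clinical semi-quantitative first-pass workflow:

1. (optional) rigid in-plane registration of every frame to a reference;
2. mean time-signal-intensity (TSI) curve per AHA segment and for a
   blood-pool ROI, in each physiological state;
3. maximum upslope of each curve — the steepest ordinary-least-squares
   slope over a short sliding window restricted to the bolus wash-in;
4. relative upslope = segment upslope / blood-pool upslope (normalizes for
   bolus shape and injection);
5. MPRI = stress relative upslope / rest relative upslope per segment,
   averaged per slice level and globally;
6. a rule-based perfusion-defect classification over (stress deficit,
   rest deficit, LGE) booleans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateDataError,
    ExtractionError,
    NoBolusError,
    ParameterError,
    WindowError,
)
from .geometry import LEVEL_LABELS, SegmentMask
from .io import PerfusionSeries
from .phantom import integer_shift

BASAL_SEGMENTS = frozenset(range(1, 7))
MID_SEGMENTS = frozenset(range(7, 13))
APICAL_SEGMENTS = frozenset(range(13, 17))


# ---------------------------------------------------------------- registration

def register_frames(
    series: PerfusionSeries, reference: int = 0, max_shift: int = 5
) -> tuple[PerfusionSeries, np.ndarray]:
    """Rigid integer-translation registration of every frame to a reference.

    For each frame the (dy, dx) in ``[-max_shift, max_shift]^2`` maximizing
    the Pearson correlation with the reference frame (all slices jointly,
    zero-filled borders) is applied.  Ties go to the smallest shift
    magnitude, then lexicographic (dy, dx).  Returns the corrected series
    and the applied shifts, shape (n_frames, 2).

    This emulates the effect of motion-corrected reconstruction on rigid
    in-plane motion; it recovers integer phantom shifts exactly in the
    noise-free case.
    """
    if not 0 <= reference < series.n_frames:
        raise ParameterError(f"reference frame {reference} out of range")
    rows, cols = series.grid_shape
    if 2 * max_shift + 1 > min(rows, cols):
        raise ParameterError("search window larger than the image")

    candidates = sorted(
        ((dy, dx) for dy in range(-max_shift, max_shift + 1)
         for dx in range(-max_shift, max_shift + 1)),
        key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]),
    )
    ref = series.data[reference]
    ref_flat = ref.ravel()
    ref_c = ref_flat - ref_flat.mean()
    ref_norm = np.sqrt(np.sum(ref_c**2))

    corrected = np.empty_like(series.data)
    shifts = np.zeros((series.n_frames, 2), dtype=int)
    for i in range(series.n_frames):
        frame = series.data[i]
        best_score, best = -np.inf, (0, 0)
        for dy, dx in candidates:
            moved = integer_shift(frame, dy, dx).ravel()
            moved_c = moved - moved.mean()
            denom = ref_norm * np.sqrt(np.sum(moved_c**2))
            score = float(np.dot(ref_c, moved_c) / denom) if denom > 0 else 0.0
            if score > best_score:
                best_score, best = score, (dy, dx)
        shifts[i] = best
        corrected[i] = integer_shift(frame, *best)
    out = PerfusionSeries(
        data=corrected,
        dt=series.dt,
        slice_levels=series.slice_levels,
        state=series.state,
        pixel_spacing=series.pixel_spacing,
        slice_thickness=series.slice_thickness,
    )
    return out, shifts


# ------------------------------------------------------------- TSI extraction

@dataclass
class TSICurveSet:
    """Per-segment and blood-pool mean-signal curves for one state."""

    state: str
    times: np.ndarray  # (n_frames,) seconds
    segments: dict[int, np.ndarray]  # AHA label -> (n_frames,) au
    blood: np.ndarray  # (n_frames,) au
    n_baseline_frames: int = 5

    def __post_init__(self) -> None:
        n = len(self.times)
        if len(self.blood) != n or any(len(c) != n for c in self.segments.values()):
            raise ParameterError("all curves must have one sample per frame")
        if not set(self.segments) <= set(range(1, 17)):
            raise ParameterError("segment IDs must be within 1..16")


def extract_tsi(
    series: PerfusionSeries,
    masks: dict[str, SegmentMask],
    blood_pool_level: str = "mid",
    n_baseline_frames: int = 5,
) -> TSICurveSet:
    """Mean signal under each segment label per frame, plus the blood pool.

    ``masks`` maps slice level -> SegmentMask on the same grid as the
    series.  The blood-pool curve comes from the designated slice's eroded
    lumen ROI (default: mid).
    """
    segments: dict[int, np.ndarray] = {}
    for level, mask in masks.items():
        z = series.slice_index(level)
        if mask.labels.shape != series.grid_shape:
            raise ExtractionError(f"mask grid {mask.labels.shape} != series grid {series.grid_shape}")
        frames = series.data[:, z]  # (n_frames, rows, cols)
        for seg in LEVEL_LABELS[level]:
            pix = mask.labels == seg
            if not pix.any():
                raise ExtractionError(f"segment {seg} ({level}) has an empty mask")
            segments[seg] = frames[:, pix].mean(axis=1)
    pool_mask = masks[blood_pool_level].blood_pool
    if not pool_mask.any():
        raise ExtractionError("blood-pool ROI is empty")
    z = series.slice_index(blood_pool_level)
    blood = series.data[:, z][:, pool_mask].mean(axis=1)
    return TSICurveSet(
        state=series.state or "unknown",
        times=series.frame_times,
        segments=segments,
        blood=blood,
        n_baseline_frames=n_baseline_frames,
    )


# ------------------------------------------------------------------- upslope

def detect_baseline(curve: np.ndarray, n_baseline: int = 5) -> tuple[float, int]:
    """Baseline level and first-enhancement index of a TSI curve.

    Baseline is the mean of the first ``n_baseline`` frames; enhancement
    starts at the first frame strictly exceeding baseline + 3*SD of those
    frames (absolute tolerance 1 au when the baseline SD is zero).
    """
    curve = np.asarray(curve, dtype=float)
    if len(curve) <= n_baseline:
        raise ParameterError("curve shorter than the baseline window")
    base = float(curve[:n_baseline].mean())
    sd = float(curve[:n_baseline].std())
    threshold = base + (3.0 * sd if sd > 0 else 1.0)
    above = np.nonzero(curve > threshold)[0]
    if len(above) == 0:
        raise NoBolusError("curve never rises above baseline (no contrast arrival)")
    return base, int(above[0])


@dataclass
class UpslopeResult:
    """Maximum upslope of one TSI curve (au/s) and the window that gave it."""

    curve_id: str
    slope: float
    window_start: int
    window_len: int
    baseline: float


def max_upslope(
    curve: np.ndarray,
    times: np.ndarray,
    k: int = 3,
    n_baseline: int = 5,
    curve_id: str = "",
) -> UpslopeResult:
    """Steepest OLS slope over any k-frame window during bolus wash-in.

    Admissible windows start at or after the first-enhancement index and
    end at or before (global-peak index + 1), excluding recirculation.
    Ties go to the earliest window.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if k < 2:
        raise ParameterError("window length k must be >= 2")
    if len(curve) != len(times):
        raise ParameterError("curve and times must have equal length")
    base, enh = detect_baseline(curve, n_baseline)
    # last index attaining the global maximum, so a flat plateau (synthetic
    # step curves) still admits windows across it
    peak = int(len(curve) - 1 - np.argmax(curve[::-1]))
    last_start = min(peak + 1 - (k - 1), len(curve) - k)
    if last_start < enh:
        raise WindowError(
            f"{curve_id or 'curve'}: fewer than {k} admissible frames between "
            f"enhancement (frame {enh}) and peak (frame {peak})"
        )
    best_slope, best_start = -np.inf, enh
    for s in range(enh, last_start + 1):
        tw = times[s : s + k]
        yw = curve[s : s + k]
        tc = tw - tw.mean()
        slope = float(np.dot(tc, yw - yw.mean()) / np.dot(tc, tc))
        if slope > best_slope:
            best_slope, best_start = slope, s
    return UpslopeResult(
        curve_id=curve_id, slope=best_slope, window_start=best_start,
        window_len=k, baseline=base,
    )


def relative_upslope(segment: UpslopeResult, blood: UpslopeResult) -> float:
    """Segment maximum upslope normalized by the blood-pool maximum upslope."""
    if blood.slope <= 0:
        raise DegenerateDataError("blood-pool maximum upslope is not positive")
    return segment.slope / blood.slope


# ---------------------------------------------------------------------- MPRI

@dataclass
class MPRIResult:
    """Relative upslopes, per-segment MPRI, level means and the global MPRI."""

    rel_upslope_rest: dict[int, float]
    rel_upslope_stress: dict[int, float]
    mpri: dict[int, float]
    level_means: dict[str, float]
    global_mpri: float
    n_segments: int
    window_len: int = 3


def _state_relative_upslopes(curves: TSICurveSet, k: int) -> dict[int, float]:
    blood = max_upslope(
        curves.blood, curves.times, k=k,
        n_baseline=curves.n_baseline_frames, curve_id=f"{curves.state} blood pool",
    )
    out: dict[int, float] = {}
    for seg in sorted(curves.segments):
        seg_up = max_upslope(
            curves.segments[seg], curves.times, k=k,
            n_baseline=curves.n_baseline_frames,
            curve_id=f"{curves.state} segment {seg}",
        )
        out[seg] = relative_upslope(seg_up, blood)
    return out


def compute_mpri(rest: TSICurveSet, stress: TSICurveSet, k: int = 3) -> MPRIResult:
    """Per-segment MPRI with level and global aggregates.

    MPRI_s = stress relative upslope / rest relative upslope; the global
    MPRI is the arithmetic mean over the segments available in both states,
    with ``n_segments`` recording how many contributed.
    """
    if set(rest.segments) != set(stress.segments):
        raise ParameterError("rest and stress curve sets cover different segments")
    rel_rest = _state_relative_upslopes(rest, k)
    rel_stress = _state_relative_upslopes(stress, k)
    mpri: dict[int, float] = {}
    for seg in sorted(rel_rest):
        if rel_rest[seg] <= 0:
            raise DegenerateDataError(f"segment {seg}: rest relative upslope is not positive")
        mpri[seg] = rel_stress[seg] / rel_rest[seg]
    level_means = {
        name: float(np.mean([m for s, m in mpri.items() if s in segs]))
        for name, segs in (
            ("basal", BASAL_SEGMENTS), ("mid", MID_SEGMENTS), ("apical", APICAL_SEGMENTS),
        )
        if any(s in segs for s in mpri)
    }
    return MPRIResult(
        rel_upslope_rest=rel_rest,
        rel_upslope_stress=rel_stress,
        mpri=mpri,
        level_means=level_means,
        global_mpri=float(np.mean(list(mpri.values()))),
        n_segments=len(mpri),
        window_len=k,
    )


# ----------------------------------------------------------- defect labelling

CLASSIFICATIONS = ("normal", "artifact", "fixed", "reversible")


def classify_defect(stress_deficit: bool, rest_deficit: bool, lge: bool) -> str:
    """Rule-based perfusion-defect classification.

    A deficit at both stress and rest is an artifact unless LGE marks scar
    in the same territory (then a fixed defect); a deficit at stress only
    is an inducible, reversible defect.  A rest-only deficit cannot be
    ischemia and is reported as artifact (extrapolation: this cell is not
    covered by the clinical rules; see docs/methods.md).
    """
    if stress_deficit and rest_deficit:
        return "fixed" if lge else "artifact"
    if stress_deficit:
        return "reversible"
    if rest_deficit:
        return "artifact"
    return "normal"


def flag_deficit_segments(
    mpri: MPRIResult, threshold: float = 0.75, state: str = "stress"
) -> dict[int, bool]:
    """Automated surrogate for a visual deficit call.

    A segment is flagged when its relative upslope in the given state falls
    below ``threshold`` times the median relative upslope of all segments
    in that state.
    """
    if not 0 < threshold < 1:
        raise ParameterError("threshold must be in (0, 1)")
    rel = mpri.rel_upslope_stress if state == "stress" else mpri.rel_upslope_rest
    med = float(np.median(list(rel.values())))
    return {seg: bool(v < threshold * med) for seg, v in sorted(rel.items())}


@dataclass
class DefectCall:
    """Classification of one segment from its deficit flags and LGE status."""

    segment: int
    stress_deficit: bool
    rest_deficit: bool
    lge: bool
    classification: str = field(init=False)

    def __post_init__(self) -> None:
        self.classification = classify_defect(self.stress_deficit, self.rest_deficit, self.lge)
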