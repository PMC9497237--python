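"""Synthetic first-pass perfusion phantom with closed-form ground truth.

The phantom emulates a rest/stress pair of dynamic short-axis acquisitions:
a gamma-variate contrast bolus fills the LV lumen (the arterial input), and
each AHA segment of the myocardial annulus enhances as a pure-uptake
compartment driven by that input with its own flow scalar F.  Because the
tissue curve is the running integral of the input, its maximum slope is
proportional to F, so the true myocardial perfusion reserve index of every
segment is exactly ``F_stress / F_rest`` — every downstream stage can be
validated against known truth without any patient data.

Deliberate simplifications (see docs/methods.md): Gaussian rather than
Rician noise, integer in-plane translation as the only motion, no washout
during the simulated window, no T1-weighting or saturation physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .geometry import (
    SegmentMask,
    SliceContours,
    circle_polygon,
    rasterize_polygon,
    segment_aha16,
    write_contours,
)
from .io import SLICE_LEVELS, PerfusionSeries, write_perfusion_nifti


@dataclass(frozen=True)
class AIFParams:
    """Gamma-variate arterial-input (blood-pool bolus) curve parameters.

    The curve is amplitude-normalized so its peak is analytically
    ``baseline + amplitude`` at ``t = onset + alpha * beta``:

        S(t) = S0 + A * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta)

    for t > t0, and S0 before the bolus arrives.
    """

    amplitude: float = 80.0  # au above baseline at peak
    onset: float = 8.0  # s
    alpha: float = 3.0  # shape, dimensionless
    beta: float = 4.0  # timescale, s
    baseline: float = 20.0  # pre-bolus blood signal, au

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("gamma-variate alpha and beta must be positive")
        if self.onset < 0 or self.amplitude < 0:
            raise ParameterError("onset and amplitude must be non-negative")


def aif_gamma_variate(t: np.ndarray, p: AIFParams) -> np.ndarray:
    """Evaluate the blood-pool bolus curve at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    if t.ndim and np.any(np.diff(t) < 0):
        raise ParameterError("time vector must be non-decreasing")
    out = np.full(t.shape, p.baseline, dtype=float)
    after = t > p.onset
    x = (t[after] - p.onset) / (p.alpha * p.beta)
    out[after] += p.amplitude * x**p.alpha * np.exp(p.alpha - (t[after] - p.onset) / p.beta)
    return out


def tissue_curve(aif: np.ndarray, flow: float, dt: float, s0_myo: float,
                 s0_blood: float) -> np.ndarray:
    """Pure-uptake myocardial enhancement driven by the arterial input.

    S_myo(t_n) = S0_myo + F * dt * sum_{i<=n} (AIF(t_i) - S0_blood)

    No washout is modelled during the first pass, so the curve's maximum
    frame-to-frame slope is F * max(AIF - S0_blood): relative upslope is
    proportional to F and true MPRI is exactly the flow ratio.
    """
    if flow <= 0:
        raise ParameterError("flow scalar must be positive")
    aif = np.asarray(aif, dtype=float)
    return s0_myo + flow * dt * np.cumsum(aif - s0_blood)


def _default_flows(value: float) -> np.ndarray:
    return np.full(16, value, dtype=float)


@dataclass
class PhantomSpec:
    """Everything needed to generate one rest/stress phantom pair.

    Defaults describe a 48x48 grid at the 2.8 mm in-plane resolution typical
    of first-pass imaging, 60 frames at 1 s, an annulus of 12/24 mm radii
    (scaled by ``apex_scale`` at the apex), and a uniform doubling of flow
    from rest to stress (true MPRI 2.0 everywhere).
    """

    grid_shape: tuple[int, int] = (48, 48)  # rows, cols
    pixel_spacing: float = 2.8  # mm
    slice_thickness: float = 8.0  # mm
    dt: float = 1.0  # s
    n_frames: int = 60
    n_baseline_frames: int = 5
    center: tuple[float, float] = (24.0, 24.0)  # (x, y) pixels
    endo_radius_mm: float = 12.0
    epi_radius_mm: float = 24.0
    apex_scale: float = 0.7
    rv_angle_deg: float = -135.0
    aif_rest: AIFParams = field(default_factory=lambda: AIFParams(amplitude=80.0))
    aif_stress: AIFParams = field(default_factory=lambda: AIFParams(amplitude=100.0))
    f_rest: np.ndarray = field(default_factory=lambda: _default_flows(0.05))
    f_stress: np.ndarray = field(default_factory=lambda: _default_flows(0.10))
    s0_myo: float = 10.0  # au
    noise_sigma: float = 1.0  # au
    motion_amplitude: int = 0  # max |shift| in pixels
    lge_flags: np.ndarray = field(default_factory=lambda: np.zeros(16, dtype=bool))
    dark_rim: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.f_rest = np.asarray(self.f_rest, dtype=float)
        self.f_stress = np.asarray(self.f_stress, dtype=float)
        self.lge_flags = np.asarray(self.lge_flags, dtype=bool)
        if self.f_rest.shape != (16,) or self.f_stress.shape != (16,):
            raise ParameterError("f_rest and f_stress must each have 16 entries")
        if np.any(self.f_rest <= 0) or np.any(self.f_stress <= 0):
            raise ParameterError("all flow scalars must be positive")
        if not self.n_baseline_frames < self.n_frames:
            raise ParameterError("n_baseline_frames must be < n_frames")
        if self.endo_radius_mm >= self.epi_radius_mm:
            raise ParameterError("endo radius must be smaller than epi radius")
        if self.noise_sigma < 0 or self.motion_amplitude < 0:
            raise ParameterError("noise sigma and motion amplitude must be >= 0")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.dt

    def contours(self) -> dict[str, SliceContours]:
        """Circular endo/epi contours per level, apex scaled down."""
        cx, cy = self.center
        rows, cols = self.grid_shape
        out: dict[str, SliceContours] = {}
        for level in SLICE_LEVELS:
            scale = self.apex_scale if level == "apex" else 1.0
            r_endo = scale * self.endo_radius_mm / self.pixel_spacing
            r_epi = scale * self.epi_radius_mm / self.pixel_spacing
            if cx - r_epi < 0 or cy - r_epi < 0 or cx + r_epi > cols - 1 or cy + r_epi > rows - 1:
                raise GeometryError("epicardial annulus exceeds the image grid")
            ang = np.deg2rad(self.rv_angle_deg)
            rv = np.array([cx + (r_epi + 2.0) * np.cos(ang), cy + (r_epi + 2.0) * np.sin(ang)])
            out[level] = SliceContours(
                level=level,
                endo=circle_polygon(cx, cy, r_endo),
                epi=circle_polygon(cx, cy, r_epi),
                rv_insertion=rv,
            )
        return out


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a generated phantom."""

    flow_ratio: np.ndarray  # (16,) F_stress / F_rest
    shifts: np.ndarray  # (n_frames, 2) applied (dy, dx) integer shifts
    f_rest: np.ndarray
    f_stress: np.ndarray
    lge_flags: np.ndarray
    noise_sigma: float
    motion_amplitude: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "flow_ratio": self.flow_ratio.tolist(),
            "shifts": self.shifts.tolist(),
            "f_rest": self.f_rest.tolist(),
            "f_stress": self.f_stress.tolist(),
            "lge_flags": self.lge_flags.astype(bool).tolist(),
            "noise_sigma": self.noise_sigma,
            "motion_amplitude": self.motion_amplitude,
            "seed": self.seed,
        }


def integer_shift(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate the last two axes by whole pixels, filling with zeros."""
    out = np.roll(frame, (dy, dx), axis=(-2, -1))
    if dy > 0:
        out[..., :dy, :] = 0.0
    elif dy < 0:
        out[..., dy:, :] = 0.0
    if dx > 0:
        out[..., :, :dx] = 0.0
    elif dx < 0:
        out[..., :, dx:] = 0.0
    return out


def _random_walk_shifts(rng: np.random.Generator, n_frames: int, amplitude: int) -> np.ndarray:
    shifts = np.zeros((n_frames, 2), dtype=int)
    if amplitude > 0:
        steps = rng.integers(-1, 2, size=(n_frames - 1, 2))
        pos = np.zeros(2, dtype=int)
        for i, step in enumerate(steps, start=1):
            pos = np.clip(pos + step, -amplitude, amplitude)
            shifts[i] = pos
    return shifts


def _render_state(
    spec: PhantomSpec,
    aif_params: AIFParams,
    flows: np.ndarray,
    masks: dict[str, SegmentMask],
    lumen: dict[str, np.ndarray],
    rim: dict[str, np.ndarray],
    shifts: np.ndarray,
    rng: np.random.Generator,
    state: str,
) -> PerfusionSeries:
    t = spec.frame_times
    aif = aif_gamma_variate(t, aif_params)
    # value table per frame: column 0 background, 1..16 segments, 17 lumen
    table = np.zeros((spec.n_frames, 18))
    for seg in range(16):
        table[:, seg + 1] = tissue_curve(
            aif, flows[seg], spec.dt, spec.s0_myo, aif_params.baseline
        )
    table[:, 17] = aif
    transit = (aif - aif_params.baseline) > 0.05 * aif_params.amplitude

    data = np.zeros((spec.n_frames, len(SLICE_LEVELS), *spec.grid_shape))
    for z, level in enumerate(SLICE_LEVELS):
        idx = masks[level].labels.astype(int).copy()
        idx[lumen[level]] = 17
        movie = table[:, idx]  # (n_frames, rows, cols)
        if spec.dark_rim:
            # subendocardial rim drops to 80% of its tissue signal during transit
            movie = movie.copy()
            rim_mask = rim[level]
            sub = movie[:, rim_mask]
            sub[transit] *= 0.8
            movie[:, rim_mask] = sub
        data[:, z] = movie
    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma, size=data.shape)
    if spec.motion_amplitude > 0:
        for i in range(spec.n_frames):
            dy, dx = shifts[i]
            if dy or dx:
                data[i] = integer_shift(data[i], int(dy), int(dx))
    return PerfusionSeries(
        data=data,
        dt=spec.dt,
        slice_levels=SLICE_LEVELS,
        state=state,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[PerfusionSeries, PerfusionSeries, dict[str, SliceContours], PhantomTruth]:
    """Generate the rest series, stress series, contours and ground truth.

    Deterministic: the same spec (including seed) reproduces identical
    arrays.  The same per-frame motion trajectory is applied to both
    states; contours are returned in the unshifted frame of reference.
    """
    contours = spec.contours()
    rng = np.random.default_rng(spec.seed)
    masks = {lvl: segment_aha16(c, spec.grid_shape) for lvl, c in contours.items()}
    lumen = {lvl: rasterize_polygon(c.endo, spec.grid_shape) for lvl, c in contours.items()}
    rim: dict[str, np.ndarray] = {}
    for lvl in SLICE_LEVELS:
        annulus = masks[lvl].labels > 0
        rim[lvl] = annulus & ndimage.binary_dilation(lumen[lvl])

    shifts = _random_walk_shifts(rng, spec.n_frames, spec.motion_amplitude)
    rest = _render_state(
        spec, spec.aif_rest, spec.f_rest, masks, lumen, rim, shifts, rng, "rest"
    )
    stress = _render_state(
        spec, spec.aif_stress, spec.f_stress, masks, lumen, rim, shifts, rng, "stress"
    )
    truth = PhantomTruth(
        flow_ratio=spec.f_stress / spec.f_rest,
        shifts=shifts,
        f_rest=spec.f_rest.copy(),
        f_stress=spec.f_stress.copy(),
        lge_flags=spec.lge_flags.copy(),
        noise_sigma=spec.noise_sigma,
        motion_amplitude=spec.motion_amplitude,
        seed=spec.seed,
    )
    return rest, stress, contours, truth


def write_phantom_bundle(
    spec: PhantomSpec, out_dir: str | Path
) -> tuple[PerfusionSeries, PerfusionSeries, dict[str, SliceContours], PhantomTruth]:
    """Generate a phantom and write rest/stress NIfTI, contours and truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rest, stress, contours, truth = generate_phantom(spec)
    write_perfusion_nifti(rest, out_dir / "rest.nii.gz")
    write_perfusion_nifti(stress, out_dir / "stress.nii.gz")
    write_contours(contours, out_dir / "contours")
    (out_dir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
    return rest, stress, contours, truth
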