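"""Dynamic perfusion series container and NIfTI round-trip.

A first-pass perfusion acquisition is a short 4D movie: three short-axis
slices (base, mid, apex) imaged once per heartbeat while a gadolinium bolus
transits the heart.  On disk we use 4D NIfTI with dimension order
(x, y, slice, time); in memory the series is held time-major as
``(frames, slices, rows, cols)`` with the frame interval taken from the
header's fourth zoom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, ParameterError

SLICE_LEVELS = ("base", "mid", "apex")


@dataclass
class PerfusionSeries:
    """One physiological state's dynamic short-axis stack.

    Attributes
    ----------
    data : ndarray, shape (n_frames, n_slices, rows, cols)
        Signal intensity in arbitrary units (au).
    dt : float
        Frame interval in seconds.
    slice_levels : tuple of str
        Anatomical level of each slice, ordered base -> apex.
    state : str or None
        "rest" or "stress" when known.
    pixel_spacing : float
        In-plane pixel size, mm.
    slice_thickness : float
        Slice thickness (plus gap), mm.
    """

    data: np.ndarray
    dt: float
    slice_levels: tuple[str, ...] = SLICE_LEVELS
    state: str | None = None
    pixel_spacing: float = 2.8
    slice_thickness: float = 8.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise FormatError(
                f"perfusion series must be 4D (frames, slices, rows, cols); got ndim={self.data.ndim}"
            )
        if not (self.dt > 0):
            raise FormatError(f"frame interval dt must be positive; got {self.dt}")
        self.slice_levels = tuple(self.slice_levels)
        if len(self.slice_levels) != self.data.shape[1]:
            raise ParameterError(
                f"{len(self.slice_levels)} slice levels for {self.data.shape[1]} slices"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (first frame at t=0)."""
        return np.arange(self.n_frames, dtype=float) * self.dt

    def slice_index(self, level: str) -> int:
        try:
            return self.slice_levels.index(level)
        except ValueError:
            raise ParameterError(f"no slice at level {level!r}") from None


def write_perfusion_nifti(series: PerfusionSeries, path: str | Path) -> Path:
    """Write a series as 4D NIfTI, dimension order (x, y, slice, time).

    Pixel spacing, slice thickness and the frame interval dt are stored in
    the header zooms so a round trip preserves the sampling geometry.
    """
    path = Path(path)
    # memory (t, z, row, col) -> nifti (x=col, y=row, z, t)
    arr = np.transpose(series.data, (3, 2, 1, 0))
    affine = np.diag(
        [series.pixel_spacing, series.pixel_spacing, series.slice_thickness, 1.0]
    )
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(
        (series.pixel_spacing, series.pixel_spacing, series.slice_thickness, series.dt)
    )
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    return path


def read_perfusion_nifti(
    path: str | Path,
    state: str | None = None,
    slice_levels: tuple[str, ...] = SLICE_LEVELS,
) -> PerfusionSeries:
    """Load a 4D dynamic series; dt comes from the header's time zoom."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"perfusion series not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4D dynamic series, got {img.ndim}D")
    zooms = img.header.get_zooms()
    dt = float(zooms[3]) if len(zooms) >= 4 else 0.0
    if dt <= 0:
        raise FormatError(f"{path}: time step (4th header zoom) must be > 0, got {dt}")
    data = np.transpose(np.asanyarray(img.dataobj), (3, 2, 1, 0)).astype(np.float64)
    return PerfusionSeries(
        data=data,
        dt=dt,
        slice_levels=slice_levels[: data.shape[1]],
        state=state,
        pixel_spacing=float(zooms[0]),
        slice_thickness=float(zooms[2]),
    )
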