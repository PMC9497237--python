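"""Contours -> AHA 16-segment masks, blood-pool ROI, and LV volumes.

The left ventricle in a short-axis slice is an annulus between a manually
traced endocardial (inner) and epicardial (outer) border.  The AHA model
divides the basal and mid-ventricular annuli into six 60-degree sectors
(segments 1-6 and 7-12) and the apical annulus into four 90-degree sectors
(13-16), with angle zero at the anterior RV-insertion landmark.

Coordinate convention (frozen so masks are bit-reproducible): 0-based pixel
indices, pixel centers at integer (x, y), x to the right, y down.  A pixel
belongs to the myocardium iff its center is on or inside the epicardial
polygon, not on or inside the endocardial polygon, and not on or inside any
papillary-exclusion polygon (even-odd rule; for the simple polygons the
contract requires, shapely's predicates coincide with it).  Sector angles
increase with atan2(y-cy, x-cx) from the RV-insertion ray; a pixel exactly
on a sector boundary goes to the lower-numbered segment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import GeometryError, LandmarkError, ParameterError

#: AHA label ranges per slice level.
LEVEL_LABELS = {
    "base": tuple(range(1, 7)),
    "mid": tuple(range(7, 13)),
    "apex": tuple(range(13, 17)),
}
#: Number of angular sectors per level (6 basal/mid, 4 apical).
LEVEL_SECTORS = {"base": 6, "mid": 6, "apex": 4}


@dataclass
class SliceContours:
    """Manual borders and landmark for one short-axis slice.

    ``endo`` and ``epi`` are (N, 2) arrays of (x, y) vertices in pixel
    coordinates (the closing edge is implicit); ``rv_insertion`` is the
    anterior RV-insertion point, on or outside the epicardial border;
    ``papillary`` polygons are excluded from the myocardium.
    """

    level: str
    endo: np.ndarray
    epi: np.ndarray
    rv_insertion: np.ndarray | None = None
    papillary: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.level not in LEVEL_LABELS:
            raise ParameterError(f"unknown slice level {self.level!r}")
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        if self.rv_insertion is not None:
            self.rv_insertion = np.asarray(self.rv_insertion, dtype=float)
        self.papillary = [np.asarray(p, dtype=float) for p in self.papillary]
        for name, poly in (("endo", self.endo), ("epi", self.epi)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise GeometryError(f"{name} contour must be an (N>=3, 2) array")

    def to_dict(self) -> dict:
        d = {
            "level": self.level,
            "endo": self.endo.tolist(),
            "epi": self.epi.tolist(),
            "papillary": [p.tolist() for p in self.papillary],
        }
        if self.rv_insertion is not None:
            d["rv_insertion"] = self.rv_insertion.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SliceContours":
        return cls(
            level=d["level"],
            endo=np.asarray(d["endo"], dtype=float),
            epi=np.asarray(d["epi"], dtype=float),
            rv_insertion=(
                np.asarray(d["rv_insertion"], dtype=float)
                if d.get("rv_insertion") is not None
                else None
            ),
            papillary=[np.asarray(p, dtype=float) for p in d.get("papillary", [])],
        )


def write_contours(contours: dict[str, SliceContours], directory: str | Path) -> None:
    """Write one ``<level>.json`` per slice into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for level, c in contours.items():
        (directory / f"{level}.json").write_text(json.dumps(c.to_dict(), indent=1))


def read_contours(directory: str | Path) -> dict[str, SliceContours]:
    directory = Path(directory)
    out: dict[str, SliceContours] = {}
    for level in LEVEL_LABELS:
        p = directory / f"{level}.json"
        if p.exists():
            out[level] = SliceContours.from_dict(json.loads(p.read_text()))
    if not out:
        raise FileNotFoundError(f"no contour JSON files (<level>.json) in {directory}")
    return out


@dataclass
class SegmentMask:
    """Integer label image for one slice plus its blood-pool ROI.

    ``labels`` holds 0 for background and the AHA segment number
    (1-6 basal, 7-12 mid, 13-16 apical) for myocardial pixels;
    ``blood_pool`` marks the eroded LV-lumen ROI used for the arterial
    input curve.
    """

    level: str
    labels: np.ndarray
    blood_pool: np.ndarray

    @property
    def present_labels(self) -> tuple[int, ...]:
        return tuple(int(v) for v in np.unique(self.labels) if v != 0)


def _polygon(points: np.ndarray, name: str) -> Polygon:
    poly = Polygon(points)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError(f"{name} polygon is degenerate or self-intersecting")
    return poly


def _pixel_centers(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = shape
    ys, xs = np.mgrid[0:rows, 0:cols]
    return xs.astype(float), ys.astype(float)


def _covers(poly: Polygon, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Point-in-polygon including the boundary, vectorized."""
    return shapely.intersects_xy(poly, xs, ys)


def rasterize_polygon(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixel centers strictly inside a polygon."""
    poly = _polygon(points, "polygon")
    xs, ys = _pixel_centers(shape)
    return shapely.contains_xy(poly, xs, ys)


def rasterize_annulus(c: SliceContours, shape: tuple[int, int]) -> np.ndarray:
    """Myocardium mask: inside epi, outside endo, outside papillary polygons."""
    endo = _polygon(c.endo, "endo")
    epi = _polygon(c.epi, "epi")
    if not epi.contains_properly(endo):
        raise GeometryError("endocardial contour must lie strictly inside the epicardial contour")
    xs, ys = _pixel_centers(shape)
    mask = _covers(epi, xs, ys) & ~_covers(endo, xs, ys)
    for pap in c.papillary:
        mask &= ~_covers(_polygon(pap, "papillary"), xs, ys)
    return mask


def segment_aha16(
    c: SliceContours, shape: tuple[int, int], blood_pool_erosion_px: float = 2.0
) -> SegmentMask:
    """Assign each myocardial pixel its AHA segment label.

    Angles are measured about the endocardial centroid, zero along the ray
    to the RV-insertion landmark, increasing with atan2(y-cy, x-cx).  Basal
    and mid slices get six 60-degree sectors mapped to labels 1-6 / 7-12 in
    standard bull's-eye order (anterior, anteroseptal, inferoseptal,
    inferior, inferolateral, anterolateral); apical slices get four
    90-degree sectors mapped to 13-16.  The blood pool is the endocardial
    polygon eroded by ``blood_pool_erosion_px`` to avoid partial-volume
    pixels at the border.
    """
    if c.rv_insertion is None:
        raise LandmarkError(f"slice {c.level!r}: RV-insertion landmark is required")
    annulus = rasterize_annulus(c, shape)
    endo = _polygon(c.endo, "endo")
    cx, cy = endo.centroid.x, endo.centroid.y

    xs, ys = _pixel_centers(shape)
    theta0 = math.atan2(c.rv_insertion[1] - cy, c.rv_insertion[0] - cx)
    rel = np.mod(np.arctan2(ys - cy, xs - cx) - theta0, 2.0 * math.pi)

    n_sect = LEVEL_SECTORS[c.level]
    width = 2.0 * math.pi / n_sect
    idx = np.floor(rel / width).astype(int)
    # exact sector-boundary ties go to the lower-numbered segment
    on_boundary = (rel > 0) & (rel == idx * width)
    idx[on_boundary] -= 1
    idx = np.clip(idx, 0, n_sect - 1)

    offset = LEVEL_LABELS[c.level][0]
    labels = np.zeros(shape, dtype=np.int16)
    labels[annulus] = offset + idx[annulus]

    pool_poly = endo.buffer(-float(blood_pool_erosion_px))
    if pool_poly.is_empty:
        blood = np.zeros(shape, dtype=bool)
    else:
        blood = shapely.contains_xy(pool_poly, xs, ys)
    return SegmentMask(level=c.level, labels=labels, blood_pool=blood)


@dataclass
class VolumeResult:
    """Ventricular volumes by summation of discs, indexed to body size."""

    lvedv_ml: float
    lvesv_ml: float
    lvef_percent: float
    bsa_m2: float
    lvedvi_ml_per_m2: float


def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2), Mosteller formula sqrt(h*w/3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ParameterError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def lv_volumes(
    endo_stacks: list[list[np.ndarray]],
    slice_thickness_mm: float,
    slice_gap_mm: float,
    pixel_spacing_mm: float,
    height_cm: float,
    weight_kg: float,
) -> VolumeResult:
    """LV volumes from endocardial contour stacks over the cardiac cycle.

    ``endo_stacks[phase][slice]`` is an (N, 2) endocardial polygon in pixel
    coordinates.  Per phase, volume = sum over slices of endo area times
    (thickness + gap) (summation of discs); end diastole / end systole are
    the max / min phase volumes.
    """
    if slice_thickness_mm <= 0 or pixel_spacing_mm <= 0 or slice_gap_mm < 0:
        raise ParameterError("spacings must be positive (gap may be zero)")
    if not endo_stacks or any(len(phase) == 0 for phase in endo_stacks):
        raise ParameterError("need at least one slice contour per phase")
    step_mm = slice_thickness_mm + slice_gap_mm
    vols_ml = []
    for phase in endo_stacks:
        area_mm2 = sum(
            _polygon(p, "endo").area * pixel_spacing_mm**2 for p in phase
        )
        vols_ml.append(area_mm2 * step_mm / 1000.0)
    lvedv = max(vols_ml)
    lvesv = min(vols_ml)
    if lvedv <= 0:
        raise GeometryError("end-diastolic volume is zero")
    bsa = mosteller_bsa(height_cm, weight_kg)
    return VolumeResult(
        lvedv_ml=lvedv,
        lvesv_ml=lvesv,
        lvef_percent=100.0 * (lvedv - lvesv) / lvedv,
        bsa_m2=bsa,
        lvedvi_ml_per_m2=lvedv / bsa,
    )


def circle_polygon(cx: float, cy: float, radius: float, n_vertices: int = 64) -> np.ndarray:
    """Regular polygon approximating a circle, (x, y) pixel coordinates."""
    if radius <= 0:
        raise ParameterError("radius must be positive")
    ang = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])
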