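"""Vessel geometry: junction segmentation, monolayer continuity,
axis/diameter measurement and lumen-circle localisation."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import filters, measure, morphology

__all__ = [
    "SegmentationMask",
    "ContinuityReport",
    "DiameterProfile",
    "VesselCircle",
    "VesselAxis",
    "segment_junctions",
    "continuity_report",
    "estimate_axis_and_diameter",
    "locate_lumen_circle",
]


@dataclass
class SegmentationMask:
    mask: np.ndarray          # bool, same shape as the source image
    threshold: float
    method: str


@dataclass
class ContinuityReport:
    n_components: int
    largest_component_fraction: float
    is_single_object: bool


@dataclass
class DiameterProfile:
    diameters_um: np.ndarray      # per valid column
    columns: np.ndarray           # column indices of the valid profile
    summary_um: float             # median over columns
    axis_angle_deg: float
    wall_rows: np.ndarray         # (n, 2) subpixel row of each wall per column


@dataclass
class VesselCircle:
    """Lumen circle in pixel coordinates with physical radius."""
    center_row: float
    center_col: float
    radius_px: float
    pixel_size_um: float

    @property
    def radius_um(self) -> float:
        return self.radius_px * self.pixel_size_um


@dataclass
class VesselAxis:
    """Straight vessel axis in physical coordinates (x, y, z in um)."""
    point_um: np.ndarray
    direction: np.ndarray      # unit vector

    def __post_init__(self):
        self.point_um = np.asarray(self.point_um, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction must be non-zero")
        self.direction = d / n

    def radial_distance(self, pos_um: np.ndarray) -> float:
        rel = np.asarray(pos_um, dtype=float) - self.point_um
        return float(np.linalg.norm(rel - np.dot(rel, self.direction) * self.direction))


def segment_junctions(
    image: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_object_px: int = 10,
) -> SegmentationMask:
    """Threshold a 2-D projection and despeckle the foreground.

    ``method="otsu"`` (default) derives the threshold from the image
    histogram; ``method="fixed"`` uses ``fixed_threshold`` verbatim.
    Objects smaller than ``min_object_px`` pixels are removed.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D projection image")
    if image.max() == image.min():
        raise ValueError("constant image: no threshold separates foreground "
                         "from background; review the input")
    if method == "otsu":
        threshold = float(filters.threshold_otsu(image))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required for method='fixed'")
        threshold = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = image >= threshold
    if min_object_px > 0:
        # removes objects of fewer than min_object_px pixels
        mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
    if not mask.any():
        raise ValueError("empty foreground after thresholding; review the "
                         f"threshold ({threshold:g}) or speckle size")
    return SegmentationMask(mask=mask, threshold=threshold, method=method)


def continuity_report(mask: SegmentationMask | np.ndarray, connectivity: int = 2) -> ContinuityReport:
    """Connected-component continuity check (8-connectivity by default)."""
    arr = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    if not arr.any():
        raise ValueError("empty mask")
    labels, n = measure.label(arr, connectivity=connectivity, return_num=True)
    sizes = np.bincount(labels.ravel())[1:]
    frac = float(sizes.max() / sizes.sum())
    return ContinuityReport(
        n_components=int(n),
        largest_component_fraction=frac,
        is_single_object=(n == 1),
    )


def _half_max_crossings(profile: np.ndarray) -> tuple[float, float] | None:
    """Outermost half-maximum crossings of a 1-D profile, subpixel.

    Returns None when a wall touches the profile ends (out of field).
    """
    half = profile.max() / 2.0
    above = profile >= half
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    first, last = idx[0], idx[-1]
    if first == 0 or last == len(profile) - 1:
        return None
    # linear interpolation across the crossing
    lo = first - 1 + (half - profile[first - 1]) / (profile[first] - profile[first - 1])
    hi = last + (profile[last] - half) / (profile[last] - profile[last + 1])
    return float(lo), float(hi)


def estimate_axis_and_diameter(
    image: np.ndarray,
    pixel_size_um: float,
    min_valid_columns: int = 10,
    min_column_mass_frac: float = 0.5,
) -> DiameterProfile:
    """Axis angle and per-column diameter of a roughly horizontal vessel.

    The axis comes from a line fit to the intensity-weighted centroid of
    each column; per-column walls are the outermost half-maximum
    crossings of the transverse profile, and the wall separation is
    corrected by cos(axis angle) to a perpendicular diameter.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D projection image")
    rows, cols = image.shape
    col_max = image.max(axis=0)
    global_max = float(image.max())
    if global_max <= 0:
        raise ValueError("blank image")
    strong = col_max >= min_column_mass_frac * global_max

    r_idx = np.arange(rows)
    diameters, wall_lo, wall_hi, centroids, valid_cols = [], [], [], [], []
    for c in np.flatnonzero(strong):
        profile = image[:, c]
        crossing = _half_max_crossings(profile)
        if crossing is None:
            continue
        lo, hi = crossing
        valid_cols.append(c)
        wall_lo.append(lo)
        wall_hi.append(hi)
        w = profile / profile.sum()
        centroids.append(float(np.dot(r_idx, w)))
        diameters.append(hi - lo)

    if not valid_cols:
        raise ValueError("no valid columns: a wall may be out of the field")
    if len(valid_cols) < min_valid_columns:
        raise ValueError(
            f"only {len(valid_cols)} valid columns (< {min_valid_columns})"
        )

    valid_cols = np.asarray(valid_cols)
    centroids = np.asarray(centroids)
    slope, _ = np.polyfit(valid_cols, centroids, 1)
    # image rows grow downward; report the angle in math convention (y up)
    axis_angle_deg = math.degrees(math.atan(-slope))
    cos_a = math.cos(math.radians(axis_angle_deg))

    diam_um = np.asarray(diameters) * pixel_size_um * cos_a
    return DiameterProfile(
        diameters_um=diam_um,
        columns=valid_cols,
        summary_um=float(np.median(diam_um)),
        axis_angle_deg=axis_angle_deg,
        wall_rows=np.column_stack([wall_lo, wall_hi]),
    )


def locate_lumen_circle(
    frame: np.ndarray,
    pixel_size_um: float,
    min_area_px: int = 50,
) -> VesselCircle:
    """Locate the bright lumen disk in an early permeability frame.

    Centroid of the largest above-threshold component plus an
    equivalent-area radius.  Requires the lumen to be brighter than the
    exterior (true at t ~ 0 of a leakage movie).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a single 2-D frame")
    if frame.max() == frame.min():
        raise ValueError("flat frame: no bright lumen region")
    threshold = filters.threshold_otsu(frame)
    mask = frame >= threshold
    labels, n = measure.label(mask, return_num=True)
    if n == 0:
        raise ValueError("no bright region above threshold")
    sizes = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(sizes)) + 1
    area = float(sizes[biggest - 1])
    if area < min_area_px:
        raise ValueError(f"largest bright region ({area:.0f} px) below "
                         f"min_area_px={min_area_px}")
    rr, cc = np.nonzero(labels == biggest)
    return VesselCircle(
        center_row=float(rr.mean()),
        center_col=float(cc.mean()),
        radius_px=math.sqrt(area / math.pi),
        pixel_size_um=pixel_size_um,
    )
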