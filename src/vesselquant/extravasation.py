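"""3-D nucleus detection and transendothelial-migration scoring.

Nuclei are detected with a band-pass + threshold + distance-transform
watershed pipeline (automating what is classically done by eye), then
classified monocyte/endothelial by size and roundness, and positioned
relative to the vessel wall by their radial excess (perpendicular
distance to the axis minus the radius).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .geometry import VesselAxis
from .stack import ImageStack

__all__ = [
    "NucleusDetection",
    "ClassifiedCell",
    "ExtravasationSummary",
    "detect_nuclei",
    "classify_cell_type",
    "classify_position",
    "summarize_vessel",
    "analyze_stack",
]


@dataclass
class NucleusDetection:
    centroid_um: tuple[float, float, float]   # (x, y, z)
    equivalent_diameter_um: float
    sphericity: float                          # sqrt(min/max inertia eigenvalue)
    peak_intensity: float


@dataclass
class ClassifiedCell:
    detection: NucleusDetection
    cell_type: str             # monocyte | endothelial
    position_class: str        # luminal_adherent | extravasated | luminal_free
    radial_excess_um: float


@dataclass
class ExtravasationSummary:
    vessel_id: str
    n_adhered: int
    n_extravasated: int
    migration_distances_um: list
    mean_distance_um: float
    median_distance_um: float


def _mad_sigma(values: np.ndarray) -> float:
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def detect_nuclei(
    stack: ImageStack,
    min_diam_um: float = 5.0,
    max_diam_um: float = 15.0,
    peak_snr: float = 5.0,
) -> list[NucleusDetection]:
    """Detect blob-like nuclei in a z-stack; returns a (possibly empty) list.

    Pipeline: difference-of-Gaussians band-pass bracketing the expected
    diameter range -> noise-scaled threshold -> anisotropy-aware
    distance-transform watershed to split touching nuclei -> per-region
    half-maximum refinement for the equivalent diameter and inertia-based
    sphericity.  z anisotropy is honored throughout via the slice step.
    """
    if stack.axis_kind != "z":
        raise ValueError("nucleus detection requires a z-stack")
    data = stack.data.astype(np.float64)
    if data.size == 0:
        raise ValueError("empty stack")
    px, dz = stack.pixel_size_um, stack.step
    spacing = np.array([dz, px, px])

    sig_lo_um = min_diam_um / 6.0
    sig_hi_um = max_diam_um
    bp = (
        ndimage.gaussian_filter(data, sig_lo_um / spacing)
        - ndimage.gaussian_filter(data, sig_hi_um / spacing)
    )
    noise = _mad_sigma(bp)
    threshold = max(peak_snr * noise, 0.2 * bp.max())
    mask = bp > threshold
    if not mask.any():
        return []

    # drop specks smaller than half the minimum nucleus volume
    min_vox = max(int((math.pi / 6) * min_diam_um**3 / (2 * dz * px * px)), 4)
    labels0, _ = ndimage.label(mask)
    sizes = np.bincount(labels0.ravel())
    mask &= sizes[labels0] >= min_vox
    if not mask.any():
        return []

    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    # light smoothing removes spurious maxima on noisy EDT ridges; the
    # depth threshold keeps only markers at least ~r_min/2 inside the mask
    edt_s = ndimage.gaussian_filter(edt, 1.0 / spacing)
    foot_r = 0.45 * min_diam_um
    footprint = np.ones(tuple(max(int(2 * foot_r / s) | 1, 5) for s in spacing))
    peaks = peak_local_max(edt_s, footprint=footprint,
                           threshold_abs=0.3 * min_diam_um,
                           labels=ndimage.label(mask)[0],
                           exclude_border=False)
    if len(peaks) == 0:
        return []
    # exactly tied plateau maxima survive any footprint; greedily merge
    # peaks closer than half a minimal nucleus
    peaks_um = peaks * spacing
    # must exceed one z-step: plateau ties on adjacent slices are duplicates
    merge_um = max(0.6 * min_diam_um, 1.2 * dz)
    merged: list[np.ndarray] = []
    for p in peaks_um:
        for i, grp in enumerate(merged):
            if np.linalg.norm(grp.mean(axis=0) - p) < merge_um:
                merged[i] = np.vstack([grp, p])
                break
        else:
            merged.append(p[np.newaxis])
    marker_vox = np.rint(np.array([g.mean(axis=0) for g in merged]) / spacing).astype(int)
    marker_vox = np.clip(marker_vox, 0, np.array(mask.shape) - 1)
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(marker_vox.T)] = np.arange(1, len(marker_vox) + 1)
    labels = watershed(-edt_s, markers, mask=mask)

    detections: list[NucleusDetection] = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, labels.max() + 1)):
        if sl is None:
            continue
        region = labels[sl] == lab
        sub = data[sl]
        peak = float(sub[region].max())
        refined = region & (sub >= 0.5 * peak)
        if not refined.any():
            continue
        coords = np.argwhere(refined).astype(float)
        coords += np.array([s.start for s in sl])
        coords_um = coords * spacing            # (z, y, x) um
        vol_um3 = refined.sum() * dz * px * px
        eq_diam = (6.0 * vol_um3 / math.pi) ** (1.0 / 3.0)

        # intensity-weighted second moments: weighting toward the bright
        # core makes the shape measure robust to watershed truncation at
        # contact faces between touching nuclei
        weights = sub[refined] - 0.5 * peak
        weights = np.clip(weights, 1e-9, None)
        mean_um = (coords_um * weights[:, None]).sum(axis=0) / weights.sum()
        centered = coords_um - mean_um
        if len(centered) >= 4:
            cov = (centered * weights[:, None]).T @ centered / weights.sum()
            # voxels are boxes, not points: without the s^2/12 term the
            # coarse z sampling deflates the z eigenvalue and sphericity
            cov += np.diag(spacing**2) / 12.0
            evals = np.sort(np.linalg.eigvalsh(cov))
            sphericity = float(math.sqrt(max(evals[0], 0.0) / evals[2])) if evals[2] > 0 else 1.0
        else:
            sphericity = 1.0
        cz, cy, cx = mean_um
        detections.append(NucleusDetection(
            centroid_um=(float(cx), float(cy), float(cz)),
            equivalent_diameter_um=float(eq_diam),
            sphericity=sphericity,
            peak_intensity=peak,
        ))
    return detections


def classify_cell_type(
    detection: NucleusDetection,
    max_diam_um: float = 9.0,
    min_sphericity: float = 0.75,
) -> str:
    """Monocyte iff small (<= max_diam_um) and round (>= min_sphericity)."""
    small = detection.equivalent_diameter_um <= max_diam_um
    round_ = detection.sphericity >= min_sphericity
    return "monocyte" if (small and round_) else "endothelial"


def classify_position(
    detection: NucleusDetection,
    axis: VesselAxis,
    radius_um: float,
    wall_tolerance_um: float = 5.0,
) -> tuple[str, float]:
    """Position class and signed radial excess relative to the wall."""
    rho = axis.radial_distance(np.asarray(detection.centroid_um))
    excess = rho - radius_um
    if excess > wall_tolerance_um:
        cls = "extravasated"
    elif excess < -wall_tolerance_um:
        cls = "luminal_free"
    else:
        cls = "luminal_adherent"
    return cls, float(excess)


def summarize_vessel(cells: list[ClassifiedCell], vessel_id: str = "vessel") -> ExtravasationSummary:
    """Monocyte counts and migration distances for one vessel."""
    monos = [c for c in cells if c.cell_type == "monocyte"]
    adhered = [c for c in monos if c.position_class == "luminal_adherent"]
    extrav = [c for c in monos if c.position_class == "extravasated"]
    distances = [c.radial_excess_um for c in extrav]
    return ExtravasationSummary(
        vessel_id=vessel_id,
        n_adhered=len(adhered),
        n_extravasated=len(extrav),
        migration_distances_um=distances,
        mean_distance_um=float(np.mean(distances)) if distances else float("nan"),
        median_distance_um=float(np.median(distances)) if distances else float("nan"),
    )


def analyze_stack(
    stack: ImageStack,
    axis: VesselAxis,
    radius_um: float,
    vessel_id: str = "vessel",
    min_diam_um: float = 5.0,
    max_diam_um: float = 15.0,
    peak_snr: float = 5.0,
    monocyte_max_diam_um: float = 9.0,
    monocyte_min_sphericity: float = 0.75,
    wall_tolerance_um: float = 5.0,
) -> tuple[pd.DataFrame, ExtravasationSummary]:
    """Detect, classify and summarise; returns (per-cell table, summary)."""
    detections = detect_nuclei(stack, min_diam_um=min_diam_um,
                               max_diam_um=max_diam_um, peak_snr=peak_snr)
    cells = []
    for det in detections:
        ctype = classify_cell_type(det, max_diam_um=monocyte_max_diam_um,
                                   min_sphericity=monocyte_min_sphericity)
        pclass, excess = classify_position(det, axis, radius_um,
                                           wall_tolerance_um=wall_tolerance_um)
        cells.append(ClassifiedCell(det, ctype, pclass, excess))

    table = pd.DataFrame([
        {
            "vessel_id": vessel_id,
            "x_um": c.detection.centroid_um[0],
            "y_um": c.detection.centroid_um[1],
            "z_um": c.detection.centroid_um[2],
            "equivalent_diameter_um": c.detection.equivalent_diameter_um,
            "sphericity": c.detection.sphericity,
            "cell_type": c.cell_type,
            "position_class": c.position_class,
            "radial_excess_um": c.radial_excess_um,
        }
        for c in cells
    ])
    return table, summarize_vessel(cells, vessel_id=vessel_id)
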