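"""Synthetic phantom generators with known ground truth.

Every assay stage in the pipeline has a matching generator here so the
estimators can be validated by parameter recovery:

* dextran leakage movies across a circular lumen wall with known
  diffusive permeability (membrane flux into a radially diffusing
  exterior, explicit finite-volume scheme with stability-checked step);
* bleach-spot advection movies with known drift velocity and diffusive
  recovery;
* oriented fiber textures with a controlled angular dispersion
  (doubled-angle von Mises law);
* two-population nuclear z-stacks with known adhered/extravasated
  counts and radial migration distances;
* 2-D projection phantoms (vessel band, junction lattice) for the
  geometry stage.

All generators are deterministic functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage, special, stats
from skimage.draw import line_aa

from .stack import ImageStack

__all__ = [
    "VesselPhantomSpec",
    "FrapPhantomSpec",
    "FiberPhantomSpec",
    "CellPhantomSpec",
    "simulate_dextran_timelapse",
    "simulate_frap_timelapse",
    "simulate_fiber_field",
    "simulate_cell_stack",
    "simulate_vessel_projection",
    "simulate_junction_lattice",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselPhantomSpec:
    """Dextran-leakage movie across a circular lumen wall.

    The lumen is held at ``lumen_intensity`` (reservoir assumption: the
    channel stays connected to dextran-filled reservoirs).  The exterior
    evolves by radially symmetric diffusion with membrane boundary flux
    ``pd_true * (C_lumen - C_wall)``.
    """

    radius_um: float = 100.0
    pd_true: float = 1.45               # um/s
    lumen_intensity: float = 1.0
    frames: int = 50
    dt_s: float = 5.0
    pixel_size_um: float = 2.0
    field_px: tuple[int, int] = (512, 512)
    center_px: tuple[float, float] | None = None   # defaults to field centre
    noise_sd: float = 0.0               # additive, fraction of lumen_intensity
    baseline: float = 0.1               # camera dark offset, fraction of
                                        # lumen_intensity; keeps additive noise
                                        # clear of the zero-clip
    shot_noise: bool = False
    diffusion_um2_s: float = 25.0       # exterior diffusivity of the tracer
    dr_um: float = 4.0                  # radial grid resolution
    max_substeps: int = 2_000_000       # explicit-step budget per frame

    def validate(self) -> None:
        if not (self.radius_um > 0):
            raise ValueError("radius_um must be > 0")
        if self.pd_true < 0:
            raise ValueError("pd_true must be >= 0")
        if self.frames < 3:
            raise ValueError("frames must be >= 3")
        if not (self.dt_s > 0 and self.pixel_size_um > 0):
            raise ValueError("dt_s and pixel_size_um must be > 0")
        field_um = min(self.field_px) * self.pixel_size_um
        if 2 * self.radius_um >= field_um:
            raise ValueError(
                f"vessel diameter {2 * self.radius_um} um exceeds field {field_um} um"
            )
        if self.diffusion_um2_s <= 0:
            raise ValueError("diffusion_um2_s must be > 0")


@dataclass(frozen=True)
class FrapPhantomSpec:
    """Advected, diffusively recovering bleach spot on a flat background.

    ``spot_radius_px`` follows the 50-pixel-diameter convention (a "50
    pixel circle" is read as diameter 50, i.e. radius 25); configurable.
    """

    spot_radius_px: float = 25.0
    spot_depth: float = 0.8             # fractional bleach, 0..1
    velocity_um_s: float = 1.0
    direction_deg: float = 0.0          # 0 = along +cols
    diffusion_recovery_um2_s: float = 2.0
    frames: int = 30
    dt_s: float = 1.0
    pixel_size_um: float = 1.0
    field_px: tuple[int, int] = (256, 256)
    background: float = 1.0
    noise_sd: float = 0.0               # fraction of background
    margin_px: float = 8.0

    def validate(self) -> None:
        if not (0 <= self.spot_depth <= 1):
            raise ValueError("spot_depth must be in [0, 1]")
        if self.frames < 5:
            raise ValueError("frames must be >= 5")
        if self.velocity_um_s < 0:
            raise ValueError("velocity_um_s must be >= 0")
        if not (self.dt_s > 0 and self.pixel_size_um > 0 and self.background > 0):
            raise ValueError("dt_s, pixel_size_um and background must be > 0")


@dataclass(frozen=True)
class FiberPhantomSpec:
    """Additive field of straight fiber segments.

    Orientations follow the doubled-angle von Mises law: the doubled
    angle ``2*theta`` is von Mises about ``2*axis_angle_deg`` with
    concentration ``kappa``; ``kappa = 0`` gives uniform orientations and
    ``kappa = inf`` perfectly parallel fibers.
    """

    n_fibers: int = 300
    axis_angle_deg: float = 0.0
    kappa: float = 2.0
    fiber_length_px: float = 48.0
    fiber_width_px: float = 2.0
    field_px: tuple[int, int] = (512, 512)
    intensity: float = 1.0
    noise_sd: float = 0.0
    margin_px: float | None = None      # defaults to half fiber length

    def validate(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0 (0 = uniform orientations)")
        if self.fiber_length_px <= 0 or self.fiber_width_px <= 0:
            raise ValueError("fiber dimensions must be > 0")


@dataclass(frozen=True)
class CellPhantomSpec:
    """Nuclear z-stack around a cylindrical vessel.

    Endothelial nuclei sit on the cylinder surface; adhered monocyte
    nuclei sit within the wall tolerance of the surface; extravasated
    monocyte nuclei sit at radial excess distances drawn from a normal
    law truncated below at the wall tolerance.
    """

    radius_um: float = 50.0
    n_endothelial: int = 50
    n_adhered: int = 6
    n_extravasated: int = 6
    migration_mean_um: float = 20.0
    migration_sd_um: float = 5.0
    endo_nucleus_diam_um: float = 12.0
    mono_nucleus_diam_um: float = 7.0
    z_step_um: float = 2.0
    pixel_size_um: float = 1.5
    length_um: float = 240.0
    wall_tolerance_um: float = 5.0
    adhered_jitter_um: float = 2.0
    noise_sd: float = 0.02
    margin_um: float = 15.0
    max_retries: int = 200

    def validate(self) -> None:
        if min(self.n_endothelial, self.n_adhered, self.n_extravasated) < 0:
            raise ValueError("counts must be >= 0")
        if self.migration_mean_um < 0:
            raise ValueError("migration_mean_um must be >= 0")
        if self.mono_nucleus_diam_um >= self.endo_nucleus_diam_um:
            raise ValueError("monocyte nuclei must be smaller than endothelial nuclei")
        if not (self.radius_um > 0 and self.z_step_um > 0 and self.pixel_size_um > 0):
            raise ValueError("radius_um, z_step_um, pixel_size_um must be > 0")


# ---------------------------------------------------------------------------
# dextran leakage movie
# ---------------------------------------------------------------------------

class _RadialLeakModel:
    """Explicit finite-volume model of C(rho, t) outside the lumen.

    Cell-centred grid on [r, R_max]; inner face carries the membrane flux
    pd*(C_lum - C_wall), outer face is no-flux.  A single explicit Euler
    substep is the affine map C -> M C + v; K substeps are compressed to
    (M^K, sum_{j<K} M^j v) by binary doubling so frames are advanced in a
    handful of matrix products while remaining *exactly* the explicit
    scheme.
    """

    def __init__(self, spec: VesselPhantomSpec, r_max_um: float):
        r, d_rho = spec.radius_um, spec.dr_um
        n = max(int(math.ceil((r_max_um - r) / d_rho)), 4)
        self.rho = r + (np.arange(n) + 0.5) * d_rho          # cell centres
        faces = r + np.arange(n + 1) * d_rho
        D, pd = spec.diffusion_um2_s, spec.pd_true

        A = np.zeros((n, n))
        b = np.zeros(n)
        inv_vol = 1.0 / (self.rho * d_rho)
        # interior diffusive faces
        for j in range(1, n):
            g = D / d_rho * faces[j]
            A[j - 1, j - 1] -= g * inv_vol[j - 1]
            A[j - 1, j] += g * inv_vol[j - 1]
            A[j, j] -= g * inv_vol[j]
            A[j, j - 1] += g * inv_vol[j]
        # membrane face at rho = r
        g0 = pd * faces[0]
        A[0, 0] -= g0 * inv_vol[0]
        b[0] = g0 * inv_vol[0] * spec.lumen_intensity
        self.A, self.b = A, b
        self.d_rho = d_rho

        diag_max = float(np.max(np.abs(np.diag(A)))) if n else 0.0
        self.dt_stable = 0.9 / diag_max if diag_max > 0 else spec.dt_s

    def frame_operator(self, dt_frame: float, max_substeps: int):
        """(M^K, w) such that one frame advances C -> M^K C + w."""
        K = max(int(math.ceil(dt_frame / self.dt_stable)), 1)
        if K > max_substeps:
            raise ValueError(
                "finite-difference stability requires "
                f"{K} substeps per frame (> max_substeps={max_substeps}); "
                "increase dr_um or max_substeps"
            )
        dt_sub = dt_frame / K
        n = len(self.b)
        M = np.eye(n) + dt_sub * self.A
        v = dt_sub * self.b
        # binary doubling of the affine map
        P = np.eye(n)
        S = np.zeros((n, n))
        base_P, base_S = M, np.eye(n)
        k = K
        while k:
            if k & 1:
                S = base_P @ S + base_S
                P = base_P @ P
            base_S = base_P @ base_S + base_S
            base_P = base_P @ base_P
            k >>= 1
        return P, S @ v, K


def simulate_dextran_timelapse(spec: VesselPhantomSpec, seed: int):
    """Render a dextran-leakage time-lapse; returns (stack, truth dict).

    The truth record stores ``pd_true``, geometry, the noise-free lumen
    total and the per-frame exterior mass of the radial solution (in
    pixel-sum units) for oracle checks.
    """
    spec.validate()
    rows, cols = spec.field_px
    px = spec.pixel_size_um
    if spec.center_px is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    else:
        center = spec.center_px

    rr, cc = np.mgrid[0:rows, 0:cols]
    rho_px_um = np.hypot(rr - center[0], cc - center[1]) * px
    lumen_mask = rho_px_um <= spec.radius_um
    # no-flux outer boundary at the inscribed radius: leaked tracer stays
    # inside the imaged frame, which the total-intensity estimator requires
    r_max = px * min(center[0], center[1],
                     rows - 1 - center[0], cols - 1 - center[1])

    if r_max < spec.radius_um + 4 * spec.dr_um:
        raise ValueError("vessel (plus radial grid margin) exceeds the field of view")
    model = _RadialLeakModel(spec, r_max)
    P, w, substeps = model.frame_operator(spec.dt_s, spec.max_substeps)

    rng = np.random.default_rng(seed)
    n_nodes = len(model.rho)
    C = np.zeros(n_nodes)
    ext_idx = ~lumen_mask
    rho_ext = rho_px_um[ext_idx]

    frames = np.empty((spec.frames, rows, cols), dtype=np.float32)
    exterior_mass = np.empty(spec.frames)
    for t in range(spec.frames):
        img = np.empty((rows, cols))
        img[lumen_mask] = spec.lumen_intensity
        # corners beyond the circular gel boundary carry no tracer, so the
        # frame total equals the leaked mass exactly
        img[ext_idx] = np.interp(rho_ext, model.rho, C, left=C[0], right=0.0)
        exterior_mass[t] = float(img[ext_idx].sum())
        img = img + spec.baseline * spec.lumen_intensity
        if spec.shot_noise:
            scale = 1000.0 / spec.lumen_intensity
            img = rng.poisson(np.clip(img, 0, None) * scale) / scale
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd * spec.lumen_intensity, img.shape)
        frames[t] = np.clip(img, 0, None)
        C = P @ C + w

    stack = ImageStack(frames, "time", px, spec.dt_s)
    truth = {
        "kind": "dextran",
        "pd_true_um_s": spec.pd_true,
        "radius_um": spec.radius_um,
        "center_px": list(center),
        "seed": int(seed),
        "n_lumen_px": int(lumen_mask.sum()),
        "i0_total": float(spec.lumen_intensity * lumen_mask.sum()),
        "exterior_mass_per_frame": exterior_mass.tolist(),
        "substeps_per_frame": substeps,
        "diffusion_um2_s": spec.diffusion_um2_s,
        "assumptions": "lumen held as constant-concentration reservoir",
        "spec": asdict(spec),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# FRAP bleach-spot movie
# ---------------------------------------------------------------------------

def simulate_frap_timelapse(spec: FrapPhantomSpec, seed: int):
    """Render an advected recovering bleach spot; returns (stack, truth)."""
    spec.validate()
    rows, cols = spec.field_px
    px = spec.pixel_size_um
    v_px = spec.velocity_um_s / px
    ang = math.radians(spec.direction_deg)
    # direction in (row, col); 0 deg points along +cols, angles CCW (y up)
    d_row, d_col = -math.sin(ang), math.cos(ang)
    total_px = v_px * spec.dt_s * (spec.frames - 1)

    c0 = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    start = c0 - 0.5 * total_px * np.array([d_row, d_col])
    end = c0 + 0.5 * total_px * np.array([d_row, d_col])
    lim = spec.spot_radius_px + spec.margin_px
    for p in (start, end):
        if not (lim <= p[0] <= rows - 1 - lim and lim <= p[1] <= cols - 1 - lim):
            raise ValueError("spot leaves the field before the final frame")

    sigma0_um = spec.spot_radius_px * px / 2.0
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:rows, 0:cols]

    frames = np.empty((spec.frames, rows, cols), dtype=np.float32)
    centers = []
    for t in range(spec.frames):
        tt = t * spec.dt_s
        ctr = start + v_px * tt * np.array([d_row, d_col])
        centers.append(ctr.copy())
        var_um2 = sigma0_um**2 + 2.0 * spec.diffusion_recovery_um2_s * tt
        depth_t = spec.spot_depth * sigma0_um**2 / var_um2
        d2_um2 = ((rr - ctr[0]) ** 2 + (cc - ctr[1]) ** 2) * px**2
        img = spec.background * (1.0 - depth_t * np.exp(-d2_um2 / (2.0 * var_um2)))
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd * spec.background, img.shape)
        frames[t] = np.clip(img, 0, None)

    stack = ImageStack(frames, "time", px, spec.dt_s)
    truth = {
        "kind": "frap",
        "velocity_um_s": spec.velocity_um_s,
        "direction_deg": spec.direction_deg,
        "centers_px": [list(c) for c in centers],
        "seed": int(seed),
        "spec": asdict(spec),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# fiber field
# ---------------------------------------------------------------------------

def draw_fiber_angles(spec: FiberPhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Fiber orientations in degrees, in [0, 180)."""
    axis = spec.axis_angle_deg
    if math.isinf(spec.kappa):
        theta = np.full(spec.n_fibers, axis, dtype=float)
    elif spec.kappa == 0:
        theta = rng.uniform(0.0, 180.0, spec.n_fibers)
    else:
        phi = rng.vonmises(0.0, spec.kappa, spec.n_fibers)   # doubled angle
        theta = axis + np.degrees(phi) / 2.0
    return np.mod(theta, 180.0)


def simulate_fiber_field(spec: FiberPhantomSpec, seed: int):
    """Render anti-aliased fiber segments; returns (image, truth)."""
    spec.validate()
    rows, cols = spec.field_px
    margin = spec.margin_px if spec.margin_px is not None else spec.fiber_length_px / 2 + 2
    if 2 * margin >= min(rows, cols):
        raise ValueError("field too small for the fiber length")

    rng = np.random.default_rng(seed)
    theta = draw_fiber_angles(spec, rng)
    cr = rng.uniform(margin, rows - 1 - margin, spec.n_fibers)
    cc_ = rng.uniform(margin, cols - 1 - margin, spec.n_fibers)

    # render on a 2x supersampled grid to suppress stair-step aliasing that
    # would leak orientation energy off the true fiber angle
    ss = 2
    big = np.zeros((rows * ss, cols * ss))
    half = spec.fiber_length_px / 2.0
    for th, r0, c0 in zip(np.radians(theta), cr, cc_):
        d_row, d_col = -math.sin(th), math.cos(th)   # angle CCW, y up
        ra = int(round(ss * (r0 - half * d_row)))
        ca = int(round(ss * (c0 - half * d_col)))
        rb = int(round(ss * (r0 + half * d_row)))
        cb = int(round(ss * (c0 + half * d_col)))
        ra, rb = np.clip([ra, rb], 0, rows * ss - 1)
        ca, cb = np.clip([ca, cb], 0, cols * ss - 1)
        ln_r, ln_c, val = line_aa(ra, ca, rb, cb)
        big[ln_r, ln_c] += val * spec.intensity
    # width profile doubles as the anti-alias filter (stair-step harmonics
    # of shallow lines otherwise leak orientation energy)
    sigma_big = ss * max(spec.fiber_width_px, 1.2) / 2.355
    big = ndimage.gaussian_filter(big, sigma_big)
    img = big.reshape(rows, ss, cols, ss).mean(axis=(1, 3))
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd * spec.intensity, img.shape)
    img = np.clip(img, 0, None)

    truth = {
        "kind": "fibers",
        "kappa": spec.kappa,
        "axis_angle_deg": spec.axis_angle_deg,
        "angles_deg": theta.tolist(),
        "seed": int(seed),
        "spec": {**asdict(spec), "kappa": float(spec.kappa)},
    }
    return img, truth


def expected_alignment_index(kappa: float) -> float:
    """Closed-form E[cos 2(theta-axis)] for the doubled-angle von Mises law."""
    if math.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(special.i1(kappa) / special.i0(kappa))


# ---------------------------------------------------------------------------
# nuclear z-stack
# ---------------------------------------------------------------------------

def _soft_sphere(patch_d_um: np.ndarray, radius_um: float, edge_um: float = 0.8):
    return 0.5 * special.erfc((patch_d_um - radius_um) / (math.sqrt(2.0) * edge_um))


def simulate_cell_stack(spec: CellPhantomSpec, seed: int):
    """Render a two-population nuclear z-stack; returns (stack, truth).

    The truth table lists every nucleus: class, position class, centroid
    (x, y, z in um) and radial excess (perpendicular distance to the
    vessel axis minus the radius).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    px, dz = spec.pixel_size_um, spec.z_step_um

    reach = spec.radius_um + spec.migration_mean_um + 4 * spec.migration_sd_um
    half_um = reach + spec.margin_um
    n_rows = int(math.ceil(2 * half_um / px))
    n_slices = int(math.ceil(2 * half_um / dz))
    n_cols = int(math.ceil(spec.length_um / px))

    y0, z0 = n_rows * px / 2.0, n_slices * dz / 2.0  # axis at (y0, z0), along x
    x_lo, x_hi = spec.margin_um, spec.length_um - spec.margin_um

    placed: list[tuple[np.ndarray, float]] = []   # (xyz um, radius um)

    def _place(rho_um: float, radius_um: float, label: str) -> np.ndarray:
        for _ in range(spec.max_retries):
            phi = rng.uniform(0, 2 * math.pi)
            x = rng.uniform(x_lo, x_hi)
            pos = np.array([x, y0 + rho_um * math.cos(phi), z0 + rho_um * math.sin(phi)])
            # nuclei are solid bodies: demand a small clearance so the
            # half-maximum surfaces of neighbours stay disjoint
            ok = all(
                np.linalg.norm(pos - q) >= 1.05 * (radius_um + qr)
                for q, qr in placed
            )
            if ok:
                placed.append((pos, radius_um))
                return pos
        raise RuntimeError(f"could not place a non-overlapping {label} nucleus; "
                           "reduce counts or enlarge the field")

    records = []

    def _add(n, cell_type, excess_fn, position_class, diam):
        for _ in range(n):
            excess = float(excess_fn())
            pos = _place(spec.radius_um + excess, diam / 2.0, cell_type)
            records.append({
                "cell_type": cell_type,
                "position_class": position_class,
                "x_um": pos[0], "y_um": pos[1], "z_um": pos[2],
                "radial_excess_um": excess,
                "diameter_um": diam,
            })

    _add(spec.n_endothelial, "endothelial", lambda: 0.0, "wall",
         spec.endo_nucleus_diam_um)
    _add(spec.n_adhered, "monocyte",
         lambda: rng.uniform(-spec.adhered_jitter_um, spec.adhered_jitter_um),
         "luminal_adherent", spec.mono_nucleus_diam_um)
    if spec.n_extravasated > 0:
        lo = spec.wall_tolerance_um + 0.5
        a = (lo - spec.migration_mean_um) / spec.migration_sd_um
        draws = iter(stats.truncnorm.rvs(
            a, np.inf, loc=spec.migration_mean_um, scale=spec.migration_sd_um,
            size=spec.n_extravasated, random_state=rng))
        _add(spec.n_extravasated, "monocyte", lambda: next(draws),
             "extravasated", spec.mono_nucleus_diam_um)

    vol = np.zeros((n_slices, n_rows, n_cols))
    zz_um = np.arange(n_slices) * dz
    yy_um = np.arange(n_rows) * px
    xx_um = np.arange(n_cols) * px
    for rec in records:
        R = rec["diameter_um"] / 2.0
        ext = R + 3.0
        zi = np.searchsorted(zz_um, [rec["z_um"] - ext, rec["z_um"] + ext])
        yi = np.searchsorted(yy_um, [rec["y_um"] - ext, rec["y_um"] + ext])
        xi = np.searchsorted(xx_um, [rec["x_um"] - ext, rec["x_um"] + ext])
        zi, yi, xi = [np.clip(i, 0, n) for i, n in zip((zi, yi, xi),
                                                       (n_slices, n_rows, n_cols))]
        lz = zz_um[zi[0]:zi[1]][:, None, None] - rec["z_um"]
        ly = yy_um[yi[0]:yi[1]][None, :, None] - rec["y_um"]
        lx = xx_um[xi[0]:xi[1]][None, None, :] - rec["x_um"]
        d = np.sqrt(lz**2 + ly**2 + lx**2)
        blob = _soft_sphere(d, R)
        region = vol[zi[0]:zi[1], yi[0]:yi[1], xi[0]:xi[1]]
        np.maximum(region, blob, out=region)   # nuclei exclude, do not sum

    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape)
    vol = np.clip(vol, 0, None)

    stack = ImageStack(vol.astype(np.float32), "z", px, dz)
    truth = {
        "kind": "cells",
        "radius_um": spec.radius_um,
        "axis_point_um": [0.0, y0, z0],
        "axis_direction": [1.0, 0.0, 0.0],
        "n_adhered_true": spec.n_adhered,
        "n_extravasated_true": spec.n_extravasated,
        "nuclei": records,
        "seed": int(seed),
        "spec": asdict(spec),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# 2-D geometry phantoms
# ---------------------------------------------------------------------------

def simulate_vessel_projection(
    diameter_um: float,
    axis_angle_deg: float = 0.0,
    pixel_size_um: float = 2.0,
    field_px: tuple[int, int] = (256, 384),
    intensity: float = 1.0,
    edge_sigma_um: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Projection of a cylindrical vessel as a smooth-edged bright band.

    The half-maximum crossings of the transverse profile sit exactly at
    the wall positions, so the band width at half maximum equals
    ``diameter_um``.  Returns (image, truth).
    """
    if diameter_um <= 0:
        raise ValueError("diameter_um must be > 0")
    rows, cols = field_px
    ang = math.radians(axis_angle_deg)
    rr, cc = np.mgrid[0:rows, 0:cols]
    d_um = np.abs(
        (rr - (rows - 1) / 2.0) * math.cos(ang)
        + (cc - (cols - 1) / 2.0) * math.sin(ang)
    ) * pixel_size_um
    R = diameter_um / 2.0
    s = edge_sigma_um * math.sqrt(2.0)
    img = intensity * 0.5 * (special.erf((R - d_um) / s) + special.erf((R + d_um) / s))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd * intensity, img.shape)
    img = np.clip(img, 0, None)
    truth = {
        "kind": "projection",
        "diameter_um": diameter_um,
        "axis_angle_deg": axis_angle_deg,
        "pixel_size_um": pixel_size_um,
        "seed": int(seed),
    }
    return img, truth


def simulate_junction_lattice(
    field_px: tuple[int, int] = (256, 256),
    spacing_px: int = 32,
    line_width_px: int = 2,
    margin_px: int = 16,
    intensity: float = 1.0,
    noise_sd: float = 0.0,
    cut: tuple[int, int, int, int] | None = None,
    seed: int = 0,
):
    """Bright junction lattice (grid of lines) on a dark background.

    ``cut = (r0, r1, c0, c1)`` zeroes a region, e.g. a horizontal band
    between two grid lines to split the lattice in two.  Returns
    (image, mask) where mask is the exact rendered foreground.
    """
    rows, cols = field_px
    mask = np.zeros((rows, cols), dtype=bool)
    half = line_width_px // 2
    lo_r, hi_r = margin_px, rows - margin_px
    lo_c, hi_c = margin_px, cols - margin_px
    for r in range(lo_r, hi_r + 1, spacing_px):
        mask[max(r - half, 0): r + half + 1, lo_c: hi_c + 1] = True
    for c in range(lo_c, hi_c + 1, spacing_px):
        mask[lo_r: hi_r + 1, max(c - half, 0): c + half + 1] = True
    if cut is not None:
        r0, r1, c0, c1 = cut
        mask[r0:r1, c0:c1] = False
    img = mask.astype(float) * intensity
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, noise_sd * intensity, img.shape), 0, None)
    return img, mask
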