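"""Diffusive permeability from dextran leakage movies.

The estimator follows the mass-balance relation

    P_d = (r / (2 * I0_total)) * dI_out_total/dt

which is exact for a 2-D disk lumen of radius ``r`` held at constant
concentration: the lumen total is ``I0 = C0 * pi r^2`` and the wall flux
is ``P_d * C0 * 2 pi r`` per unit depth, so ``dI_out/dt = 2 P_d I0 / r``.
The relation assumes the exterior concentration at the wall stays small
compared to the lumen (early-time / membrane-limited regime); once
tracer accumulates against the wall, any estimator built only from the
two totals under-reads P_d.  The automatic fit window restricts the fit
to early frames for that reason.

The estimator is invariant to affine intensity gain of the stack: both
the slope and the lumen total scale together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import VesselCircle, locate_lumen_circle
from .stack import ImageStack

__all__ = [
    "IntensityTrace",
    "PdResult",
    "extract_traces",
    "fit_leak_rate",
    "compute_pd",
    "measure_permeability",
]


@dataclass
class IntensityTrace:
    t: np.ndarray               # seconds
    i_in_total: np.ndarray      # summed lumen intensity per frame
    i_out_total: np.ndarray     # summed exterior intensity per frame
    background: float           # per-pixel background level subtracted
    n_lumen_px: int = 0         # pixels in the (eroded) lumen ROI
    lumen_area_px: float = 0.0  # full pi r^2 lumen area in pixels

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.i_in_total = np.asarray(self.i_in_total, dtype=float)
        self.i_out_total = np.asarray(self.i_out_total, dtype=float)
        if len(self.t) < 3:
            raise ValueError("need at least 3 frames")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class PdResult:
    pd_um_s: float
    r_um: float
    i0_ref: float
    slope: float                # dI_out/dt, intensity units / s
    window: tuple[int, int]     # [frame_a, frame_b)
    r_squared: float
    clipped_negative: bool = False


def extract_traces(
    stack: ImageStack,
    circle: VesselCircle,
    background: str = "first-frame-exterior",
    fixed_background: float | None = None,
    guard_px: int = 2,
) -> IntensityTrace:
    """Lumen and exterior intensity totals per frame.

    Lumen ROI: circle eroded by ``guard_px``.  Exterior ROI: everything
    outside the circle dilated by ``guard_px`` (the guard band keeps the
    wall itself out of both ROIs).  The background (mean exterior
    intensity of frame 0 by default) is subtracted from both totals,
    which are clipped at zero.
    """
    if stack.axis_kind != "time":
        raise ValueError("permeability requires a time-lapse stack")
    rows, cols = stack.frame_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    rho = np.hypot(rr - circle.center_row, cc - circle.center_col)
    lumen = rho <= circle.radius_px - guard_px
    exterior = rho > circle.radius_px + guard_px
    if not lumen.any():
        raise ValueError("guard band consumed the lumen ROI")
    if not exterior.any():
        raise ValueError("guard band consumed the exterior ROI")

    data = stack.data.astype(np.float64)
    if background == "first-frame-exterior":
        bg = float(data[0][exterior].mean())
    elif background == "fixed":
        if fixed_background is None:
            raise ValueError("fixed_background required for background='fixed'")
        bg = float(fixed_background)
    else:
        raise ValueError(f"unknown background mode {background!r}")

    i_in = data[:, lumen].sum(axis=1) - bg * lumen.sum()
    i_out = data[:, exterior].sum(axis=1) - bg * exterior.sum()
    if np.median(i_out) < -0.05 * np.abs(i_out).max():
        raise ValueError("exterior trace is negative-dominated after "
                         "background subtraction; check the background mode")
    return IntensityTrace(
        t=stack.times(),
        i_in_total=np.clip(i_in, 0, None),
        i_out_total=np.clip(i_out, 0, None),
        background=bg,
        n_lumen_px=int(lumen.sum()),
        lumen_area_px=float(np.pi * circle.radius_px**2),
    )


def _auto_window(i_out: np.ndarray, fraction: float, min_frames: int) -> tuple[int, int]:
    """Longest initial run with I_out below ``fraction`` of the final value,
    at least ``min_frames`` long; falls back to the first half."""
    n = len(i_out)
    final = i_out[-1]
    if final <= 0:
        return 0, max(n // 2, 3)
    below = i_out <= fraction * final
    k = 0
    while k < n and below[k]:
        k += 1
    k = max(k, min_frames)
    if k >= n:
        k = max(n // 2, 3)
    return 0, min(k, n)


def fit_leak_rate(
    trace: IntensityTrace,
    window: str | tuple[int, int] = "auto",
    auto_fraction: float = 0.2,
    auto_min_frames: int = 5,
) -> tuple[float, float, tuple[int, int]]:
    """OLS slope of I_out_total vs t on the fit window.

    Returns ``(slope, r_squared, (a, b))`` with the window as frame
    indices ``[a, b)``.
    """
    if window == "auto":
        a, b = _auto_window(trace.i_out_total, auto_fraction, auto_min_frames)
    else:
        a, b = int(window[0]), int(window[1])
    if b - a < 3:
        raise ValueError(f"fit window [{a}, {b}) has fewer than 3 frames")
    t = trace.t[a:b]
    y = trace.i_out_total[a:b]
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), max(min(r2, 1.0), 0.0), (a, b)


def compute_pd(
    r_um: float,
    i0_ref: float,
    slope: float,
    window: tuple[int, int] = (0, 0),
    r_squared: float = float("nan"),
) -> PdResult:
    """P_d = (r / (2 I0)) * slope, in um/s; negative slopes clip to 0."""
    if i0_ref <= 0:
        raise ValueError("i0_ref must be > 0")
    if r_um <= 0:
        raise ValueError("r_um must be > 0")
    clipped = slope < 0
    pd = 0.0 if clipped else (r_um / (2.0 * i0_ref)) * slope
    return PdResult(
        pd_um_s=pd, r_um=r_um, i0_ref=i0_ref, slope=slope,
        window=window, r_squared=r_squared, clipped_negative=clipped,
    )


def measure_permeability(
    stack: ImageStack,
    circle: VesselCircle | None = None,
    radius_um: float | None = None,
    window: str | tuple[int, int] = "auto",
    background: str = "first-frame-exterior",
    fixed_background: float | None = None,
    guard_px: int = 2,
    auto_fraction: float = 0.2,
    auto_min_frames: int = 5,
) -> PdResult:
    """Full pipeline: locate lumen (unless given), extract traces, fit,
    apply the mass-balance relation.

    ``i0_ref`` is the mean lumen total over the fit window.  When
    ``radius_um`` is supplied it overrides the area-equivalent radius of
    the located circle (the physical radius entering the formula).
    """
    if circle is None:
        circle = locate_lumen_circle(stack.data[0], stack.pixel_size_um)
    trace = extract_traces(stack, circle, background=background,
                           fixed_background=fixed_background, guard_px=guard_px)
    slope, r2, win = fit_leak_rate(trace, window=window,
                                   auto_fraction=auto_fraction,
                                   auto_min_frames=auto_min_frames)
    # reference lumen total over the *full* pi r^2 disk: the guard-band
    # erosion gives an unbiased per-pixel lumen level but undercounts the
    # area, so rescale the ROI total to the true lumen area
    i0_ref = float(trace.i_in_total[win[0]:win[1]].mean()
                   * trace.lumen_area_px / trace.n_lumen_px)
    r = radius_um if radius_um is not None else circle.radius_um
    return compute_pd(r, i0_ref, slope, window=win, r_squared=r2)
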