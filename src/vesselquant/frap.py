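"""Bleach-spot tracking and Darcy hydraulic permeability.

A photobleached spot advected by interstitial flow is tracked frame by
frame with a subpixel radially symmetric dip fit; the drift velocity and
the applied hydrostatic head give the hydraulic permeability through
Darcy's law, k = v * mu * L / dP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .config import MMH2O_TO_PA
from .stack import ImageStack

__all__ = [
    "SpotTrack",
    "VelocityResult",
    "DarcyResult",
    "SpotDetectionError",
    "detect_spot",
    "track_spot",
    "fit_velocity",
    "darcy_permeability",
]

STANDARD_HEADS_MMH2O = (5.0, 10.0, 20.0)


class SpotDetectionError(RuntimeError):
    """No credible intensity dip found in a frame."""


@dataclass
class SpotTrack:
    t: np.ndarray                    # seconds, retained frames only
    centers_px: np.ndarray           # (n, 2) subpixel (row, col)
    residuals: np.ndarray            # per-frame RMS fit residual
    frame_indices: np.ndarray        # original indices of retained frames
    failed_frames: list = field(default_factory=list)
    pixel_size_um: float = 1.0


@dataclass
class VelocityResult:
    v_um_s: float
    direction: tuple[float, float]   # unit (row, col); (0, 0) when static
    r_squared: float


@dataclass
class DarcyResult:
    k_m2: float
    v_um_s: float
    delta_p_pa: float
    head_mmh2o: float
    mu_pa_s: float
    gap_l_um: float
    porosity: float = 1.0
    zero_flow: bool = False


def _dip_model(params, rr, cc):
    b0, amp, r0, c0, sigma = params
    return b0 - amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))


def detect_spot(
    frame: np.ndarray,
    prior_center: tuple[float, float] | None = None,
    search_radius_px: float = 30.0,
    background: float | None = None,
    noise_sd: float | None = None,
    noise_k: float = 3.0,
) -> tuple[tuple[float, float], float]:
    """Subpixel centre of an intensity dip; returns ((row, col), residual).

    Candidate pixels must fall below ``background - noise_k * noise_sd``
    (background defaults to the frame median, noise to a MAD estimate);
    the centre is refined by a least-squares fit of an offset-minus-
    Gaussian dip model seeded at the deficit-weighted centroid.
    """
    frame = np.asarray(frame, dtype=float)
    if background is None:
        background = float(np.median(frame))
    if noise_sd is None:
        noise_sd = float(1.4826 * np.median(np.abs(frame - background)))
    floor = background - noise_k * max(noise_sd, 1e-12)

    rows, cols = frame.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    candidates = frame < floor
    if prior_center is not None:
        near = np.hypot(rr - prior_center[0], cc - prior_center[1]) <= search_radius_px
        candidates &= near
    if not candidates.any():
        raise SpotDetectionError(
            f"no pixels below background - {noise_k} * noise_sd"
        )

    deficit = np.where(candidates, background - frame, 0.0)
    total = deficit.sum()
    r_init = float((rr * deficit).sum() / total)
    c_init = float((cc * deficit).sum() / total)

    # fit on a window around the initial centre
    n_cand = int(candidates.sum())
    half = max(int(2.5 * math.sqrt(n_cand / math.pi)), 8)
    r_lo, r_hi = max(int(r_init) - half, 0), min(int(r_init) + half + 1, rows)
    c_lo, c_hi = max(int(c_init) - half, 0), min(int(c_init) + half + 1, cols)
    sub = frame[r_lo:r_hi, c_lo:c_hi]
    srr, scc = np.mgrid[r_lo:r_hi, c_lo:c_hi]

    amp0 = max(background - frame.min(), 1e-9)
    sigma0 = max(math.sqrt(n_cand / math.pi) / 1.5, 1.5)
    p0 = [background, amp0, r_init, c_init, sigma0]
    bounds = (
        [-np.inf, 0.0, r_lo - 2.0, c_lo - 2.0, 0.5],
        [np.inf, np.inf, r_hi + 2.0, c_hi + 2.0, max(rows, cols)],
    )
    fit = least_squares(
        lambda p: (_dip_model(p, srr, scc) - sub).ravel(), p0, bounds=bounds
    )
    b0, amp, r0, c0, sigma = fit.x
    residual = float(np.sqrt(np.mean(fit.fun**2)))
    return (float(r0), float(c0)), residual


def track_spot(
    stack: ImageStack,
    search_radius_px: float = 30.0,
    noise_k: float = 3.0,
    max_consecutive_failures: int = 3,
    min_track_frames: int = 5,
) -> SpotTrack:
    """Track the dip through a time-lapse, frame by frame.

    Each frame uses the previous centre as a spatial prior.  The track
    ends early after ``max_consecutive_failures`` consecutive failures
    (diffusive recovery erased the spot); individual failed frames are
    flagged, never silently interpolated.
    """
    if stack.axis_kind != "time":
        raise ValueError("spot tracking requires a time-lapse stack")
    if stack.n_frames < min_track_frames:
        raise ValueError(f"need at least {min_track_frames} frames")

    times, centers, residuals, kept, failed = [], [], [], [], []
    prior = None
    consecutive = 0
    for i in range(stack.n_frames):
        try:
            center, resid = detect_spot(
                stack.data[i], prior_center=prior,
                search_radius_px=search_radius_px, noise_k=noise_k,
            )
        except SpotDetectionError:
            failed.append(i)
            consecutive += 1
            if consecutive >= max_consecutive_failures:
                break
            continue
        consecutive = 0
        prior = center
        times.append(i * stack.step)
        centers.append(center)
        residuals.append(resid)
        kept.append(i)

    if len(kept) < min_track_frames:
        raise ValueError(
            f"only {len(kept)} frames with a detectable spot "
            f"(< {min_track_frames})"
        )
    return SpotTrack(
        t=np.asarray(times),
        centers_px=np.asarray(centers),
        residuals=np.asarray(residuals),
        frame_indices=np.asarray(kept),
        failed_frames=failed,
        pixel_size_um=stack.pixel_size_um,
    )


def fit_velocity(track: SpotTrack, min_frames: int = 5) -> VelocityResult:
    """Drift velocity from separate OLS lines of row(t) and col(t)."""
    if len(track.t) < min_frames:
        raise ValueError(f"need at least {min_frames} retained centres")
    t = track.t
    if np.ptp(t) == 0:
        raise ValueError("degenerate time vector")
    slope_r = np.polyfit(t, track.centers_px[:, 0], 1)[0]
    slope_c = np.polyfit(t, track.centers_px[:, 1], 1)[0]
    speed_px = math.hypot(slope_r, slope_c)
    v = speed_px * track.pixel_size_um

    if speed_px > 0:
        direction = (slope_r / speed_px, slope_c / speed_px)
        proj = track.centers_px[:, 0] * direction[0] + track.centers_px[:, 1] * direction[1]
        slope_p, icpt = np.polyfit(t, proj, 1)
        resid = proj - (slope_p * t + icpt)
        ss_tot = float(np.sum((proj - proj.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    else:
        direction = (0.0, 0.0)
        r2 = 1.0
    return VelocityResult(v_um_s=float(v), direction=direction,
                          r_squared=max(min(r2, 1.0), 0.0))


def darcy_permeability(
    v_um_s: float,
    head_mmh2o: float,
    gap_l_um: float,
    mu_pa_s: float = 0.7e-3,
    porosity: float = 1.0,
) -> DarcyResult:
    """Hydraulic permeability k = q * mu * L / dP in m^2.

    The tracked spot velocity is taken as the superficial Darcy flux
    (``porosity = 1`` by default); set ``porosity < 1`` to convert an
    interstitial velocity to a superficial one (q = porosity * v).
    """
    if head_mmh2o <= 0:
        raise ValueError("head_mmh2o must be > 0")
    if gap_l_um <= 0:
        raise ValueError("gap_l_um must be > 0")
    if mu_pa_s <= 0:
        raise ValueError("mu_pa_s must be > 0")
    if not (0 < porosity <= 1):
        raise ValueError("porosity must be in (0, 1]")
    if v_um_s < 0:
        raise ValueError("v_um_s must be >= 0")
    if head_mmh2o not in STANDARD_HEADS_MMH2O:
        warnings.warn(
            f"head {head_mmh2o} mmH2O outside the standard set "
            f"{STANDARD_HEADS_MMH2O}", stacklevel=2,
        )
    delta_p = head_mmh2o * MMH2O_TO_PA
    q_m_s = porosity * v_um_s * 1e-6
    k = q_m_s * mu_pa_s * gap_l_um * 1e-6 / delta_p
    return DarcyResult(
        k_m2=float(k), v_um_s=float(v_um_s), delta_p_pa=float(delta_p),
        head_mmh2o=float(head_mmh2o), mu_pa_s=float(mu_pa_s),
        gap_l_um=float(gap_l_um), porosity=float(porosity),
        zero_flow=(v_um_s == 0),
    )
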