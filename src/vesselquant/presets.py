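"""Named phantom presets encoding the reference condition means.

Each preset bundles a generator kind, its spec parameters and the
ground-truth targets the pipeline should recover.  The table is
immutable within a release; ``get_preset`` returns deep copies.

Diffusive-permeability presets use a fast exterior diffusivity
(1e5 um^2/s, quasi-well-mixed gel) so the slope estimator operates in
its membrane-limited validity regime; with slow tracer diffusion the
wall concentration builds up within a few frames and any estimator
based only on lumen/exterior totals is biased low (see the estimator
docs).  The diffusivity is part of the preset spec and freely
overridable.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .phantoms import (
    CellPhantomSpec,
    FiberPhantomSpec,
    VesselPhantomSpec,
    simulate_cell_stack,
    simulate_dextran_timelapse,
    simulate_fiber_field,
    simulate_vessel_projection,
)

__all__ = ["Preset", "get_preset", "list_presets", "simulate_preset"]

_FAST_GEL_D = 1.0e5   # um^2/s, validation regime (see module docstring)


@dataclass(frozen=True)
class Preset:
    name: str
    kind: str            # dextran | cells | projection | fibers
    params: dict = field(default_factory=dict)
    truth_targets: dict = field(default_factory=dict)
    description: str = ""


_PRESETS: dict[str, Preset] = {}


def _register(preset: Preset) -> None:
    _PRESETS[preset.name] = preset


for _name, _pd in [("static-2.5mg", 1.45), ("flow-2.5mg", 0.10), ("flow-6mg", 0.60)]:
    _register(Preset(
        name=_name,
        kind="dextran",
        params=dict(radius_um=100.0, pd_true=_pd, frames=50, dt_s=5.0,
                    pixel_size_um=2.0, field_px=(512, 512), noise_sd=0.02,
                    diffusion_um2_s=_FAST_GEL_D, dr_um=8.0),
        truth_targets={"pd_true_um_s": _pd},
        description=f"dextran leakage movie, Pd = {_pd} um/s",
    ))

_register(Preset(
    name="migration-20um",
    kind="cells",
    params=dict(n_extravasated=30, migration_mean_um=20.0, migration_sd_um=5.0,
                n_adhered=5, n_endothelial=40),
    truth_targets={"migration_mean_um": 20.0},
    description="30 extravasated monocytes at mean radial excess 20 um",
))

_register(Preset(
    name="counts-static",
    kind="cells",
    params=dict(adhered_range=(3, 10), extravasated_range=(5, 20),
                n_endothelial=40),
    truth_targets={"adhered_max": 10},
    description="static condition counts: adhered ~ U{3..10}, extravasated ~ U{5..20}",
))

_register(Preset(
    name="counts-flow",
    kind="cells",
    params=dict(adhered_range=(5, 20), extravasated_range=(1, 10),
                n_endothelial=40),
    truth_targets={"adhered_max": 20},
    description="flow condition counts: adhered ~ U{5..20}, extravasated ~ U{1..10}",
))

_register(Preset(
    name="diam-hi",
    kind="projection",
    params=dict(diameter_um=250.0, pixel_size_um=2.0, field_px=(320, 384),
                noise_sd=0.0),
    truth_targets={"diameter_um": 250.0},
    description="vessel projection, diameter 250 um",
))

_register(Preset(
    name="diam-lo",
    kind="projection",
    params=dict(diameter_um=125.0, pixel_size_um=2.0, field_px=(320, 384),
                noise_sd=0.0),
    truth_targets={"diameter_um": 125.0},
    description="vessel projection, diameter 125 um",
))

_register(Preset(
    name="aligned",
    kind="fibers",
    params=dict(kappa=math.inf, axis_angle_deg=0.0, n_fibers=400,
                fiber_length_px=120.0, fiber_width_px=1.0,
                field_px=(576, 576), noise_sd=0.0),
    truth_targets={"alpha": 1.0},
    description="perfectly parallel fiber field",
))

_register(Preset(
    name="random",
    kind="fibers",
    params=dict(kappa=0.0, axis_angle_deg=0.0, n_fibers=400,
                fiber_length_px=120.0, fiber_width_px=1.0,
                field_px=(576, 576), noise_sd=0.0),
    truth_targets={"alpha": 0.0},
    description="isotropic fiber field",
))


def list_presets() -> list[str]:
    return sorted(_PRESETS)


def get_preset(name: str) -> Preset:
    try:
        preset = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(list_presets())}"
        ) from None
    return copy.deepcopy(preset)


def simulate_preset(name: str, seed: int):
    """Generate the phantom for a preset; returns (stack_or_image, truth).

    Count presets draw their per-replicate counts from the stated
    discrete uniform ranges using the same seed stream that drives the
    renderer, so a (preset, seed) pair is fully reproducible.
    """
    preset = get_preset(name)
    params = dict(preset.params)
    if preset.kind == "dextran":
        stack, truth = simulate_dextran_timelapse(VesselPhantomSpec(**params), seed)
    elif preset.kind == "cells":
        rng = np.random.default_rng([seed, 0xCE11])
        if "adhered_range" in params:
            lo, hi = params.pop("adhered_range")
            params["n_adhered"] = int(rng.integers(lo, hi + 1))
        if "extravasated_range" in params:
            lo, hi = params.pop("extravasated_range")
            params["n_extravasated"] = int(rng.integers(lo, hi + 1))
        stack, truth = simulate_cell_stack(CellPhantomSpec(**params), seed)
    elif preset.kind == "projection":
        stack, truth = simulate_vessel_projection(seed=seed, **params)
    elif preset.kind == "fibers":
        stack, truth = simulate_fiber_field(FiberPhantomSpec(**params), seed)
    else:  # pragma: no cover - table is static
        raise ValueError(f"unhandled preset kind {preset.kind!r}")
    truth["preset"] = name
    truth["truth_targets"] = preset.truth_targets
    return stack, truth
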