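"""Shared fixtures.

Expensive phantom simulations are session-scoped so the recovery-style
tests and the acceptance suite reuse a single run.
"""

from __future__ import annotations

import numpy as np
import pytest

from vesselquant.extravasation import analyze_stack
from vesselquant.geometry import VesselAxis
from vesselquant.permeability import measure_permeability
from vesselquant.phantoms import (
    CellPhantomSpec,
    VesselPhantomSpec,
    simulate_cell_stack,
    simulate_dextran_timelapse,
)
from vesselquant.presets import simulate_preset

PD_CONDITIONS = {"static-2.5mg": 1.45, "flow-6mg": 0.60, "flow-2.5mg": 0.10}
PD_SEEDS = tuple(range(1, 9))


@pytest.fixture(scope="session")
def pd_recovery():
    """{preset: {"true": pd, "estimates": [per seed 1..8]}} from the full
    locate -> extract -> fit -> mass-balance pipeline."""
    out = {}
    for preset, pd_true in PD_CONDITIONS.items():
        estimates = []
        for seed in PD_SEEDS:
            stack, truth = simulate_preset(preset, seed)
            res = measure_permeability(stack, radius_um=truth["radius_um"])
            estimates.append(res.pd_um_s)
        out[preset] = {"true": pd_true, "estimates": estimates}
    return out


@pytest.fixture(scope="session")
def cell_axis():
    def _axis(truth):
        return VesselAxis(point_um=truth["axis_point_um"],
                          direction=truth["axis_direction"])
    return _axis


@pytest.fixture(scope="session")
def counts_static_runs(cell_axis):
    """Measured vs true adhered counts on the counts-static preset, seeds 1-8."""
    runs = []
    for seed in range(1, 9):
        stack, truth = simulate_preset("counts-static", seed)
        _, summary = analyze_stack(stack, cell_axis(truth), truth["radius_um"])
        runs.append({"seed": seed, "true": truth["n_adhered_true"],
                     "measured": summary.n_adhered})
    return runs


@pytest.fixture(scope="session")
def migration_runs(cell_axis):
    """Recovered migration-distance means on migration-20um, seeds 1-5."""
    means = []
    for seed in range(1, 6):
        stack, truth = simulate_preset("migration-20um", seed)
        _, summary = analyze_stack(stack, cell_axis(truth), truth["radius_um"])
        means.append(summary.mean_distance_um)
    return means


@pytest.fixture(scope="session")
def noisefree_cell_run(cell_axis):
    """A noise-free stack with 6 adhered + 3 extravasated, analysed."""
    spec = CellPhantomSpec(n_endothelial=40, n_adhered=6, n_extravasated=3,
                           noise_sd=0.0)
    stack, truth = simulate_cell_stack(spec, 1)
    table, summary = analyze_stack(stack, cell_axis(truth), truth["radius_um"])
    return stack, truth, table, summary


@pytest.fixture(scope="session")
def oracle_dextran():
    """Noise-free membrane-limited leakage movie for the mass-balance oracle."""
    spec = VesselPhantomSpec(radius_um=75.0, pd_true=0.5, noise_sd=0.0,
                             diffusion_um2_s=2.0e5, dr_um=8.0,
                             field_px=(640, 640))
    return simulate_dextran_timelapse(spec, 1), spec
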