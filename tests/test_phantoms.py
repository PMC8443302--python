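import math

import numpy as np
import pandas as pd
import pytest
from scipy import special

from vesselquant.phantoms import (
    CellPhantomSpec,
    FiberPhantomSpec,
    FrapPhantomSpec,
    VesselPhantomSpec,
    draw_fiber_angles,
    expected_alignment_index,
    simulate_cell_stack,
    simulate_dextran_timelapse,
    simulate_fiber_field,
    simulate_frap_timelapse,
    simulate_junction_lattice,
    simulate_vessel_projection,
)
from vesselquant.presets import get_preset, list_presets, simulate_preset

SMALL_DEXTRAN = dict(radius_um=60.0, field_px=(256, 256), frames=10,
                     diffusion_um2_s=1e5, dr_um=8.0)


# ---------------------------------------------------------------- dextran

def test_dextran_zero_pd_exterior_constant():
    spec = VesselPhantomSpec(pd_true=0.0, noise_sd=0.0, **SMALL_DEXTRAN)
    stack, truth = simulate_dextran_timelapse(spec, 0)
    em = np.array(truth["exterior_mass_per_frame"])
    np.testing.assert_allclose(em, 0.0, atol=1e-9)
    # rendered frames identical up to the constant baseline
    np.testing.assert_allclose(stack.data[0], stack.data[-1], atol=1e-6)


def test_dextran_early_slope_matches_mass_balance(oracle_dextran):
    """Exterior growth rate equals 2 Pd I0 / r in the early-time window."""
    (stack, truth), spec = oracle_dextran
    em = np.array(truth["exterior_mass_per_frame"])
    t = np.arange(spec.frames) * spec.dt_s
    k = 10
    slope = np.polyfit(t[:k], em[:k], 1)[0]
    expected = 2.0 * spec.pd_true * truth["i0_total"] / spec.radius_um
    assert slope == pytest.approx(expected, rel=0.02)


def test_dextran_static_preset_early_growth_linear():
    stack, truth = simulate_preset("static-2.5mg", 1)
    assert truth["pd_true_um_s"] == 1.45
    em = np.array(truth["exterior_mass_per_frame"])
    t = np.arange(len(em)) * 5.0
    k = 8
    slope, icpt = np.polyfit(t[:k], em[:k], 1)
    resid = em[:k] - (slope * t[:k] + icpt)
    r2 = 1 - resid.var() / em[:k].var()
    assert r2 > 0.999


def test_dextran_deterministic_bitwise():
    spec = VesselPhantomSpec(pd_true=0.5, noise_sd=0.05, **SMALL_DEXTRAN)
    s1, _ = simulate_dextran_timelapse(spec, 3)
    s2, _ = simulate_dextran_timelapse(spec, 3)
    np.testing.assert_array_equal(s1.data, s2.data)
    s3, _ = simulate_dextran_timelapse(spec, 4)
    assert not np.array_equal(s1.data, s3.data)


def test_dextran_stability_refusal_names_substeps():
    spec = VesselPhantomSpec(pd_true=0.5, noise_sd=0.0, max_substeps=10,
                             **SMALL_DEXTRAN)
    with pytest.raises(ValueError, match=r"\d+ substeps"):
        simulate_dextran_timelapse(spec, 0)


def test_dextran_vessel_exceeds_field():
    spec = VesselPhantomSpec(radius_um=300.0, field_px=(256, 256),
                             pixel_size_um=2.0)
    with pytest.raises(ValueError, match="field"):
        spec.validate()


def test_dextran_estimator_insensitive_to_diffusivity():
    from vesselquant.permeability import measure_permeability

    results = []
    for D in (1e5, 3e5):
        spec = VesselPhantomSpec(pd_true=0.6, noise_sd=0.0, radius_um=60.0,
                                 field_px=(320, 320), diffusion_um2_s=D,
                                 dr_um=8.0)
        stack, _ = simulate_dextran_timelapse(spec, 1)
        results.append(measure_permeability(stack, radius_um=60.0).pd_um_s)
    assert results[0] == pytest.approx(results[1], rel=0.03)


# ------------------------------------------------------------------- FRAP

def test_frap_static_spot_centroid_stationary():
    spec = FrapPhantomSpec(velocity_um_s=0.0, noise_sd=0.0, frames=10)
    stack, truth = simulate_frap_timelapse(spec, 0)
    centers = np.array(truth["centers_px"])
    np.testing.assert_allclose(centers - centers[0], 0.0, atol=1e-12)
    # with recovery disabled the frames are strictly identical
    frozen = FrapPhantomSpec(velocity_um_s=0.0, noise_sd=0.0, frames=10,
                             diffusion_recovery_um2_s=0.0)
    fstack, _ = simulate_frap_timelapse(frozen, 0)
    np.testing.assert_array_equal(fstack.data[0], fstack.data[-1])


def test_frap_kinematics_identity():
    spec = FrapPhantomSpec(velocity_um_s=1.0, dt_s=1.0, frames=30,
                           pixel_size_um=1.0, noise_sd=0.0)
    _, truth = simulate_frap_timelapse(spec, 0)
    centers = np.array(truth["centers_px"])
    disp = np.linalg.norm(centers[-1] - centers[0])
    assert disp == pytest.approx(29.0, abs=1e-9)  # 29 intervals at 1 um/s


def test_frap_centroid_trajectory_exactly_linear():
    spec = FrapPhantomSpec(velocity_um_s=0.8, direction_deg=20.0, noise_sd=0.0)
    _, truth = simulate_frap_timelapse(spec, 0)
    centers = np.array(truth["centers_px"])
    t = np.arange(len(centers))
    for dim in (0, 1):
        resid = centers[:, dim] - np.polyval(np.polyfit(t, centers[:, dim], 1), t)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)


def test_frap_flat_when_depth_zero():
    spec = FrapPhantomSpec(spot_depth=0.0, noise_sd=0.0, frames=5)
    stack, _ = simulate_frap_timelapse(spec, 0)
    assert np.ptp(stack.data) == 0.0


def test_frap_spot_leaving_field_refused():
    spec = FrapPhantomSpec(velocity_um_s=20.0, frames=30, field_px=(128, 128))
    with pytest.raises(ValueError, match="leaves the field"):
        simulate_frap_timelapse(spec, 0)


# ------------------------------------------------------------------ fibers

def test_fiber_parallel_limit():
    spec = FiberPhantomSpec(kappa=math.inf, axis_angle_deg=35.0, n_fibers=50,
                            field_px=(256, 256))
    _, truth = simulate_fiber_field(spec, 1)
    assert np.allclose(truth["angles_deg"], 35.0)


def test_fiber_uniform_limit():
    spec = FiberPhantomSpec(kappa=0.0, n_fibers=4000, field_px=(256, 256))
    rng = np.random.default_rng(1)
    theta = draw_fiber_angles(spec, rng)
    # doubled-angle resultant of a uniform sample is near zero
    resultant = np.abs(np.mean(np.exp(2j * np.radians(theta))))
    assert resultant < 0.05


def test_fiber_vonmises_closed_form():
    """Angle-population mean of cos 2(theta-axis) matches I1(k)/I0(k)."""
    spec = FiberPhantomSpec(kappa=2.0, axis_angle_deg=10.0, n_fibers=5000)
    rng = np.random.default_rng(7)
    theta = draw_fiber_angles(spec, rng)
    mc = np.mean(np.cos(2 * np.radians(theta - 10.0)))
    expected = float(special.i1(2.0) / special.i0(2.0))
    assert expected == pytest.approx(0.698, abs=0.002)
    assert mc == pytest.approx(expected, abs=0.03)


def test_expected_alignment_index_limits():
    assert expected_alignment_index(math.inf) == 1.0
    assert expected_alignment_index(0.0) == 0.0
    assert 0 < expected_alignment_index(2.0) < 1


def test_fiber_field_deterministic():
    spec = FiberPhantomSpec(n_fibers=40, field_px=(256, 256), noise_sd=0.01)
    a, _ = simulate_fiber_field(spec, 5)
    b, _ = simulate_fiber_field(spec, 5)
    np.testing.assert_array_equal(a, b)


# ------------------------------------------------------------------- cells

def test_cells_empty_monocytes():
    spec = CellPhantomSpec(n_endothelial=10, n_adhered=0, n_extravasated=0,
                           noise_sd=0.0)
    _, truth = simulate_cell_stack(spec, 0)
    table = pd.DataFrame(truth["nuclei"])
    assert set(table["cell_type"]) == {"endothelial"}


def test_cells_migration_truth_mean_near_target():
    _, truth = simulate_preset("migration-20um", 1)
    table = pd.DataFrame(truth["nuclei"])
    ex = table[table["position_class"] == "extravasated"]["radial_excess_um"]
    assert len(ex) == 30
    assert ex.mean() == pytest.approx(20.0, abs=3.0)


def test_cells_adhered_at_wall_by_construction():
    spec = CellPhantomSpec(n_endothelial=0, n_adhered=1, n_extravasated=0,
                           adhered_jitter_um=0.0, noise_sd=0.0)
    _, truth = simulate_cell_stack(spec, 0)
    (rec,) = truth["nuclei"]
    assert rec["position_class"] == "luminal_adherent"
    assert rec["radial_excess_um"] == 0.0


def test_cells_overcrowding_names_class():
    spec = CellPhantomSpec(n_endothelial=0, n_adhered=500, n_extravasated=0,
                           length_um=60.0, radius_um=20.0, max_retries=20,
                           migration_mean_um=0.0, migration_sd_um=1.0)
    with pytest.raises(RuntimeError, match="monocyte"):
        simulate_cell_stack(spec, 0)


def test_cells_mono_smaller_than_endo_enforced():
    with pytest.raises(ValueError, match="smaller"):
        CellPhantomSpec(mono_nucleus_diam_um=12.0,
                        endo_nucleus_diam_um=12.0).validate()


# ------------------------------------------------- 2-D geometry phantoms

def test_projection_half_max_width_is_diameter():
    img, _ = simulate_vessel_projection(150.0, pixel_size_um=2.0,
                                        field_px=(256, 256))
    mid = img[:, 128]
    above = np.flatnonzero(mid >= mid.max() / 2)
    width_um = (above[-1] - above[0]) * 2.0
    assert width_um == pytest.approx(150.0, abs=4.0)


def test_lattice_cut_splits_mask():
    _, mask = simulate_junction_lattice()
    _, mask_cut = simulate_junction_lattice(cut=(100, 120, 0, 256))
    assert mask.sum() > mask_cut.sum()


# ------------------------------------------------------------------ presets

def test_preset_table_contents():
    expected = {"static-2.5mg", "flow-2.5mg", "flow-6mg", "migration-20um",
                "counts-static", "counts-flow", "diam-hi", "diam-lo",
                "aligned", "random"}
    assert expected <= set(list_presets())
    assert get_preset("flow-2.5mg").params["pd_true"] == 0.10
    assert get_preset("flow-6mg").params["pd_true"] == 0.60
    assert get_preset("static-2.5mg").params["pd_true"] == 1.45
    assert get_preset("diam-hi").params["diameter_um"] == 250.0
    assert get_preset("diam-lo").params["diameter_um"] == 125.0
    assert get_preset("migration-20um").params["migration_mean_um"] == 20.0


def test_preset_unknown_name_lists_valid():
    with pytest.raises(KeyError, match="valid presets"):
        get_preset("no-such-preset")


def test_counts_preset_ranges():
    for seed in range(1, 9):
        _, truth = simulate_preset("counts-static", seed)
        assert 3 <= truth["n_adhered_true"] <= 10
        assert 5 <= truth["n_extravasated_true"] <= 20
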