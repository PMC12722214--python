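"""Bloch-McConnell engine: unit conversions, relaxation, exchange, spectra."""

import numpy as np
import pytest

from cestmrf import (MagnetizationState, SaturationEvent, TissueModel,
                     base_tissue, evolve_state, ppm_to_angular_frequency,
                     simulate_batch, simulate_trajectory, simulate_zspectrum,
                     zspectrum_protocol)
from cestmrf.physics import absorption_lineshape
from cestmrf.pools import Pool
from cestmrf.schedules import AcquisitionSchedule, ScheduleEntry

from conftest import two_pool_rk4_evolve, two_pool_steady_state_z


@pytest.mark.parametrize("offset, b0, expected_hz", [
    (0.0, 7.0, 0.0),
    (1.0, 7.0, 298.0348),          # 42.5764 MHz/T x 7 T x 1e-6
    (-3.5, 7.0, -1043.1218),
])
def test_ppm_conversion(offset, b0, expected_hz):
    assert ppm_to_angular_frequency(offset, b0) == pytest.approx(
        2 * np.pi * expected_hz, rel=1e-6)


def test_ppm_conversion_rejects_nonpositive_field():
    with pytest.raises(ValueError):
        ppm_to_angular_frequency(1.0, 0.0)


def test_free_relaxation_reaches_equilibrium(two_pool_tissue):
    """With B1 = 0 every longitudinal component returns to equilibrium."""
    state = MagnetizationState(free=np.zeros((2, 3)), z_semisolid=None,
                               pool_names=("water", "amide"))
    out = evolve_state(state, two_pool_tissue,
                       SaturationEvent(0.0, 0.0, 10 * two_pool_tissue.water_t1))
    assert out.water_z == pytest.approx(1.0, abs=1e-3)
    assert out.free[1, 2] == pytest.approx(0.003, rel=1e-3)


def test_far_off_resonance_saturation_is_inert():
    """No exchangeable pools + saturation 100 ppm away leaves water alone."""
    tissue = TissueModel(water_t1=1.8, water_t2=0.075, solute_pools=[
        Pool("amide", 3.5, 1.0, 0.04, 200.0, 0.0)])
    eq = MagnetizationState.equilibrium(tissue)
    sat = evolve_state(eq, tissue, SaturationEvent(2.0, 100.0, 3.0))
    ref = evolve_state(eq, tissue, SaturationEvent(0.0, 100.0, 3.0))
    assert sat.water_z >= 0.999 * ref.water_z


def test_two_pool_steady_state_matches_linear_solve(two_pool_tissue):
    """Long CW saturation converges to the independently solved steady state
    (20 randomized parameter sets, <=1% relative)."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        tissue = TissueModel(
            water_t1=rng.uniform(1.2, 3.0), water_t2=rng.uniform(0.04, 0.12),
            solute_pools=[Pool("s", rng.uniform(1.0, 4.0), 1.0,
                               rng.uniform(0.01, 0.2),
                               rng.uniform(20, 2000), rng.uniform(1e-4, 0.01))])
        b1 = rng.uniform(0.5, 5.0)
        offset = rng.uniform(-5, 5)
        eq = MagnetizationState.equilibrium(tissue)
        out = evolve_state(eq, tissue, SaturationEvent(b1, offset, 30.0))
        oracle = two_pool_steady_state_z(b1, offset, tissue)
        assert out.water_z == pytest.approx(oracle, rel=0.01)


def test_matrix_exponential_matches_fine_step_integration(two_pool_tissue):
    """Eigendecomposition propagation vs fine-step (1e-6 s) RK4
    integration, <=1e-6 absolute in water z, on randomized events."""
    rng = np.random.default_rng(7)
    pool = two_pool_tissue.solute_pools[0]
    for _ in range(10):
        b1 = rng.uniform(0.5, 6.0)
        offset = rng.uniform(-5, 5)
        duration = rng.uniform(0.02, 0.05)
        eq = MagnetizationState.equilibrium(two_pool_tissue)
        out = evolve_state(eq, two_pool_tissue,
                           SaturationEvent(b1, offset, duration))
        state6 = np.array([0, 0, 1.0, 0, 0, pool.volume_fraction])
        ref = two_pool_rk4_evolve(state6, b1, offset, two_pool_tissue,
                                  duration, step=1e-6)
        assert abs(out.water_z - ref[2]) <= 1e-6


def test_relaxation_monotone_no_overshoot(two_pool_tissue):
    """With B1 = 0 longitudinal recovery approaches equilibrium monotonically
    and never exceeds it beyond solver tolerance."""
    state = MagnetizationState(free=np.zeros((2, 3)), z_semisolid=None,
                               pool_names=("water", "amide"))
    previous = 0.0
    for t in np.linspace(0.1, 10.0, 25):
        out = evolve_state(state, two_pool_tissue,
                           SaturationEvent(0.0, 0.0, float(t)))
        assert out.water_z >= previous - 1e-9
        assert out.water_z <= 1.0 + 1e-9
        previous = out.water_z


def test_steady_state_forgets_initial_condition(two_pool_tissue):
    ev = SaturationEvent(2.0, 3.5, 10 * two_pool_tissue.water_t1)
    eq = MagnetizationState.equilibrium(two_pool_tissue)
    zero = MagnetizationState(free=np.zeros((2, 3)), z_semisolid=None,
                              pool_names=("water", "amide"))
    out_a = evolve_state(eq, two_pool_tissue, ev)
    out_b = evolve_state(zero, two_pool_tissue, ev)
    assert np.allclose(out_a.free, out_b.free, atol=1e-6)


def test_zero_fraction_pool_is_invisible(mt_schedule):
    """A pool with f_s = 0 leaves the trajectory identical to the model
    without that pool."""
    with_pool = TissueModel(1.8, 0.075, [Pool("amide", 3.5, 1.0, 0.04,
                                              200.0, 0.0)])
    without = TissueModel(1.8, 0.075, [])
    tr_a = simulate_trajectory(with_pool, mt_schedule).values
    tr_b = simulate_trajectory(without, mt_schedule).values
    assert np.max(np.abs(tr_a - tr_b)) <= 1e-9


def test_unsaturated_schedule_gives_flat_trajectory(full_tissue):
    """Zero saturation power + full TR recovery: all 31 values equal to 1%."""
    entries = [ScheduleEntry(None, 15.0, 0.020)]
    entries += [ScheduleEntry(SaturationEvent(0.0, 3.5, 2.5), 15.0, 0.020)
                for _ in range(30)]
    sched = AcquisitionSchedule(entries=entries)
    values = simulate_trajectory(full_tissue, sched).values
    assert np.ptp(values) / values[0] < 0.01


def test_amide_fraction_monotonically_deepens_saturation(mt_schedule):
    """Saturated entries at +3.5 ppm are non-increasing in amide f_s."""
    from cestmrf import default_schedule
    sched = default_schedule("amide")
    previous = None
    for f in (0.001, 0.004, 0.008):
        tissue = base_tissue(solutes=("amide",),
                             amide={"volume_fraction": f})
        values = simulate_trajectory(tissue, sched).values[1:]
        if previous is not None:
            assert np.all(values <= previous + 1e-12)
        previous = values


def test_batch_matches_single(full_tissue, mt_schedule):
    """The batched path is bit-identical to per-tissue simulation."""
    f_vals = np.array([0.05, 0.10, 0.20])
    batch = simulate_batch(full_tissue, {"f_ss": f_vals}, mt_schedule)
    for i, f in enumerate(f_vals):
        tissue = full_tissue.with_pool("ss", volume_fraction=float(f))
        single = simulate_trajectory(tissue, mt_schedule).values
        assert np.array_equal(batch[i], single)


class TestZSpectrum:
    def test_water_only_symmetry(self):
        tissue = TissueModel(water_t1=1.8, water_t2=0.075)
        protocol = zspectrum_protocol(0.3, 3.0, increment_ppm=0.25,
                                      sweep=(1.0, -1.0))
        z = simulate_zspectrum(tissue, protocol)
        zs = dict(zip(np.round(z.offsets, 3), z.z_values))
        for x in (0.25, 0.5, 0.75, 1.0):
            assert zs[x] == pytest.approx(zs[-x], abs=1e-6)

    def test_b0_shift_moves_the_minimum(self):
        tissue = TissueModel(water_t1=1.8, water_t2=0.075, b0_shift=0.1)
        protocol = zspectrum_protocol(0.3, 3.0, increment_ppm=0.1,
                                      sweep=(1.0, -1.0))
        z = simulate_zspectrum(tissue, protocol)
        from cestmrf import wassr_b0
        assert wassr_b0(z) == pytest.approx(0.1, abs=0.005)

    def test_amide_pool_creates_downfield_asymmetry(self, two_pool_tissue):
        protocol = zspectrum_protocol(0.7, 3.0)
        z = simulate_zspectrum(two_pool_tissue, protocol)
        downfield = z.interpolate(np.linspace(3.0, 4.0, 21)).min()
        upfield = z.interpolate(np.linspace(-4.0, -3.0, 21)).min()
        assert downfield < upfield

    def test_z_values_are_normalized(self, full_tissue):
        protocol = zspectrum_protocol(1.5, 4.0, increment_ppm=1.0)
        z = simulate_zspectrum(full_tissue, protocol)
        assert np.all(z.z_values > 0) and np.all(z.z_values <= 1.0 + 1e-9)


class TestLineshape:
    def test_lorentzian_closed_form(self):
        t2 = 1e-5
        delta = 2 * np.pi * 1000.0
        expected = (t2 / np.pi) / (1 + (delta * t2) ** 2)
        assert absorption_lineshape(delta, t2, "lorentzian") == pytest.approx(
            expected, rel=1e-12)

    def test_super_lorentzian_positive_and_continuous_at_cut(self):
        t2 = 1e-5
        cut = ppm_to_angular_frequency(1.0, 7.0)
        deltas = np.linspace(0.2 * cut, 3 * cut, 200)
        g = absorption_lineshape(deltas, t2, "super_lorentzian")
        assert np.all(g > 0)
        just_in = absorption_lineshape(cut * 0.999, t2, "super_lorentzian")
        just_out = absorption_lineshape(cut * 1.001, t2, "super_lorentzian")
        assert just_in == pytest.approx(just_out, rel=0.01)


def test_invalid_inputs_raise(two_pool_tissue):
    with pytest.raises(ValueError):
        SaturationEvent(2.0, 3.5, -1.0).validate()
    with pytest.raises(ValueError):
        TissueModel(water_t1=0.05, water_t2=0.075).validate()
    with pytest.raises(ValueError):
        TissueModel(1.8, 0.075, [Pool("x", 3.5, 1.0, 0.04, 200.0, 1.5)]).validate()
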