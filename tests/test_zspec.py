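"""Z-spectrum metrics: closed forms, WASSR, smoothing, Lorentzian fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cestmrf import (LorentzianDecomposition, ZSpectrum, aacid, arex,
                     b0_correct, delta_st, fit_multipool_lorentzian, glucest,
                     mtr, mtr_asym, mtr_rex, smooth_zspectrum, wassr_b0)


def make_spectrum(fn, hi=7.0, lo=-7.0, step=0.25, **kw):
    offsets = np.arange(hi, lo - step / 2, -step)
    return ZSpectrum(offsets=offsets, z_values=fn(offsets), **kw)


def lorentzian(x, amp, width, center):
    return amp * (width / 2) ** 2 / ((width / 2) ** 2 + (x - center) ** 2)


@pytest.fixture
def synthetic_spectrum():
    """Water + amide dips, analytically known."""
    return make_spectrum(
        lambda x: 1 - lorentzian(x, 0.7, 1.8, 0.0) - lorentzian(x, 0.06, 1.2, 3.5))


class TestClosedFormMetrics:
    def test_mtr_values(self):
        z = make_spectrum(lambda x: np.where(np.isclose(x, 3.5), 0.7, 0.9))
        assert mtr(z, 3.5) == pytest.approx(0.3)
        flat = make_spectrum(lambda x: np.ones_like(x))
        assert mtr(flat, 2.0) == pytest.approx(0.0)
        zero = make_spectrum(lambda x: np.zeros_like(x))
        assert mtr(zero, 2.0) == pytest.approx(1.0)

    def test_mtr_asym_values(self):
        z = make_spectrum(
            lambda x: np.select([np.isclose(x, 3.5), np.isclose(x, -3.5)],
                                [0.7, 0.8], 0.9))
        assert mtr_asym(z, 3.5) == pytest.approx(0.1)
        assert mtr_asym(z, 0.0) == pytest.approx(0.0)
        sym = make_spectrum(lambda x: 1 - lorentzian(x, 0.5, 2.0, 0.0))
        assert mtr_asym(sym, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_delta_st_values(self):
        z = make_spectrum(
            lambda x: np.select([np.isclose(x, 7.0), np.isclose(x, -3.5)],
                                [0.9, 0.75], 0.85))
        assert delta_st(z, -3.5) == pytest.approx(0.15)
        flat = make_spectrum(lambda x: np.full_like(x, 0.8))
        assert delta_st(flat, 3.5) == pytest.approx(0.0)
        inverted = make_spectrum(
            lambda x: np.select([np.isclose(x, 7.0), np.isclose(x, 3.5)],
                                [0.7, 0.9], 0.8))
        assert delta_st(inverted, 3.5) < 0

    def test_glucest_values(self):
        z = make_spectrum(
            lambda x: np.select([np.isclose(x, -3.0), np.isclose(x, 3.0)],
                                [0.8, 0.6], 0.9))
        assert glucest(z) == pytest.approx(25.0)
        sym = make_spectrum(lambda x: 1 - lorentzian(x, 0.5, 2.0, 0.0))
        assert glucest(sym) == pytest.approx(0.0, abs=1e-9)

    def test_glucest_zero_reference_rejected(self):
        z = make_spectrum(lambda x: np.where(np.isclose(x, -3.0), 0.0, 0.5))
        with pytest.raises(ZeroDivisionError):
            glucest(z)

    def test_aacid_values(self):
        z = make_spectrum(
            lambda x: np.select(
                [np.isclose(x, 3.5), np.isclose(x, 2.75), np.isclose(x, 6.0)],
                [0.5, 0.6, 0.9], 0.8))
        # 0.5 * (0.9 - 0.6) / (0.6 * (0.9 - 0.5)) = 0.625
        assert aacid(z) == pytest.approx(0.625)

    def test_aacid_zero_denominator_rejected(self):
        z = make_spectrum(
            lambda x: np.select(
                [np.isclose(x, 3.5), np.isclose(x, 2.75), np.isclose(x, 6.0)],
                [0.9, 0.6, 0.9], 0.8))
        with pytest.raises(ZeroDivisionError):
            aacid(z)

    def test_mtr_rex_and_arex(self):
        # Z_lab = 0.5, Z_ref = 0.8 -> 1/0.5 - 1/0.8 = 0.75; AREX = 0.75/1.5
        decomp = LorentzianDecomposition(pools={
            "water": {"amplitude": 0.2, "width": 2.0, "center": 0.0},
            "amide": {"amplitude": 0.3, "width": 2.0, "center": 3.5},
        }, residual=0.0)
        val = mtr_rex(decomp, "amide", 3.5)
        z_lab = float(decomp.z_lab(3.5))
        z_ref = float(decomp.z_ref(3.5, "amide"))
        assert val == pytest.approx(1 / z_lab - 1 / z_ref)
        assert arex(0.75, 1.5) == pytest.approx(0.5)
        assert arex(0.0, 1.5) == 0.0
        with pytest.raises(ValueError):
            arex(0.75, 0.0)

    def test_mtr_rex_zero_amplitude_pool(self):
        decomp = LorentzianDecomposition(pools={
            "water": {"amplitude": 0.5, "width": 2.0, "center": 0.0},
            "amide": {"amplitude": 0.0, "width": 2.0, "center": 3.5},
        }, residual=0.0)
        assert mtr_rex(decomp, "amide", 3.5) == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_mtr_asym_identity_on_random_spectra(seed):
    """MTR_asym(w) == MTR(+w) - MTR(-w) identically."""
    rng = np.random.default_rng(seed)
    offsets = np.arange(7.0, -7.01, -0.25)
    z = ZSpectrum(offsets, rng.uniform(0.1, 1.0, offsets.size))
    for w in rng.uniform(0.0, 6.9, 5):
        assert mtr_asym(z, w) == pytest.approx(
            mtr(z, w) - mtr(z, -w), abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
def test_aacid_scale_invariance(seed, scale):
    """AACID is a ratio of ratios: invariant to overall spectrum scaling."""
    rng = np.random.default_rng(seed)
    offsets = np.arange(7.0, -7.01, -0.2)
    values = rng.uniform(0.2, 1.0, offsets.size)
    z1 = ZSpectrum(offsets, values)
    z2 = ZSpectrum(offsets, values * scale)
    assert aacid(z2) == pytest.approx(aacid(z1), rel=1e-9)


class TestWassr:
    def test_centered_spectrum_gives_zero(self):
        z = make_spectrum(lambda x: 1 - lorentzian(x, 0.9, 0.6, 0.0),
                          hi=1.0, lo=-1.0, step=0.1)
        assert wassr_b0(z) == pytest.approx(0.0, abs=1e-3)

    def test_constructed_shift_recovered(self):
        z = make_spectrum(lambda x: 1 - lorentzian(x, 0.9, 0.6, 0.1),
                          hi=1.0, lo=-1.0, step=0.1)
        assert wassr_b0(z) == pytest.approx(0.1, abs=1e-3)

    def test_monotone_spectrum_flagged(self):
        z = make_spectrum(lambda x: 0.5 + 0.1 * x, hi=1.0, lo=-1.0, step=0.1)
        with pytest.raises(ValueError):
            wassr_b0(z)


class TestB0Correction:
    def test_zero_shift_is_identity(self, synthetic_spectrum):
        out = b0_correct(synthetic_spectrum, 0.0)
        assert np.allclose(out.z_values, synthetic_spectrum.z_values)

    def test_round_trip_recovers_spectrum(self):
        shift = 0.15
        shifted = make_spectrum(
            lambda x: 1 - lorentzian(x, 0.7, 1.8, shift)
            - lorentzian(x, 0.06, 1.2, 3.5 + shift))
        corrected = b0_correct(shifted, shift)
        reference = make_spectrum(
            lambda x: 1 - lorentzian(x, 0.7, 1.8, 0.0)
            - lorentzian(x, 0.06, 1.2, 3.5))
        good = np.isfinite(corrected.z_values)
        assert np.max(np.abs(corrected.z_values[good]
                             - reference.z_values[good])) <= 1e-3

    def test_excessive_shift_rejected(self, synthetic_spectrum):
        with pytest.raises(ValueError):
            b0_correct(synthetic_spectrum, 1.5)


class TestSmoothing:
    def test_zero_smoothing_reproduces_nodes(self, synthetic_spectrum):
        out = smooth_zspectrum(synthetic_spectrum, smoothing=0.0)
        assert np.allclose(out.z_values, synthetic_spectrum.z_values,
                           atol=1e-9)

    def test_noise_reduced(self, synthetic_spectrum):
        rng = np.random.default_rng(3)
        noisy = ZSpectrum(synthetic_spectrum.offsets,
                          synthetic_spectrum.z_values
                          + rng.normal(0, 0.01, synthetic_spectrum.offsets.size))
        out = smooth_zspectrum(noisy, smoothing=1e-3)
        resid_before = np.std(noisy.z_values - synthetic_spectrum.z_values)
        resid_after = np.std(out.z_values - synthetic_spectrum.z_values)
        assert resid_after < resid_before


class TestLorentzianFit:
    def test_two_known_pools_recovered(self):
        truth = {"water": (0.75, 2.0, 0.05), "amide": (0.05, 1.5, 3.45)}
        z = make_spectrum(
            lambda x: 1 - lorentzian(x, *truth["water"][0:1], truth["water"][1],
                                     truth["water"][2])
            - lorentzian(x, truth["amide"][0], truth["amide"][1],
                         truth["amide"][2]))
        pools = {
            "water": (0.0, 0.8, 1.4, (0.0, 1.0), (0.3, 10.0), 0.3),
            "amide": (3.5, 0.02, 1.5, (0.0, 0.3), (0.4, 6.0), 0.3),
        }
        decomp = fit_multipool_lorentzian(z, pools=pools)
        for name, (amp, width, center) in truth.items():
            assert decomp.pools[name]["amplitude"] == pytest.approx(amp, rel=0.01)
            assert decomp.pools[name]["width"] == pytest.approx(width, rel=0.01)
            assert decomp.pools[name]["center"] == pytest.approx(center, abs=0.02)

    def test_flat_spectrum_gives_zero_amplitudes(self):
        z = make_spectrum(lambda x: np.ones_like(x))
        decomp = fit_multipool_lorentzian(z)
        for name, pool in decomp.pools.items():
            if name != "water":
                assert pool["amplitude"] <= 1e-6

    def test_noisy_amplitudes_within_20_percent(self):
        """Seeded 0.005-noise realization; fit restricted to the pools the
        synthetic spectrum actually contains."""
        rng = np.random.default_rng(11)
        clean = make_spectrum(
            lambda x: 1 - lorentzian(x, 0.75, 2.0, 0.0)
            - lorentzian(x, 0.05, 1.5, 3.5) - lorentzian(x, 0.06, 3.0, -3.5))
        noisy = ZSpectrum(clean.offsets,
                          clean.z_values + rng.normal(0, 0.005,
                                                      clean.offsets.size))
        from cestmrf.zspec import DEFAULT_POOLS
        pools = {k: DEFAULT_POOLS[k] for k in ("water", "amide", "rnoe")}
        decomp = fit_multipool_lorentzian(noisy, pools=pools)
        assert decomp.pools["water"]["amplitude"] == pytest.approx(0.75, rel=0.2)
        assert decomp.pools["amide"]["amplitude"] == pytest.approx(0.05, rel=0.2)
        assert decomp.pools["rnoe"]["amplitude"] == pytest.approx(0.06, rel=0.2)


def test_mtr_rex_antisymmetry_and_sign():
    """mtr_rex >= 0 whenever Z_ref >= Z_lab > 0."""
    rng = np.random.default_rng(21)
    for _ in range(20):
        amp_w = rng.uniform(0.2, 0.7)
        amp_a = rng.uniform(0.0, 0.2)
        decomp = LorentzianDecomposition(pools={
            "water": {"amplitude": amp_w, "width": 2.0, "center": 0.0},
            "amide": {"amplitude": amp_a, "width": 1.5, "center": 3.5},
        }, residual=0.0)
        assert mtr_rex(decomp, "amide", 3.5) >= 0


def test_end_to_end_amide_metric_chain():
    """Simulated spectra: MTR, MTR_Rex and AREX at +3.5 ppm all increase
    strictly with the amide volume fraction."""
    from cestmrf import base_tissue, simulate_zspectrum, zspectrum_protocol

    protocol = zspectrum_protocol(0.7, 3.0)
    mtr_vals, rex_vals, arex_vals = [], [], []
    for f in (0.002, 0.005, 0.009):
        tissue = base_tissue(solutes=("amide",), semisolid=False,
                             amide={"volume_fraction": f})
        z = simulate_zspectrum(tissue, protocol)
        decomp = fit_multipool_lorentzian(z)
        mtr_vals.append(mtr(z, 3.5))
        rex = mtr_rex(decomp, "amide", 3.5)
        rex_vals.append(rex)
        arex_vals.append(arex(rex, tissue.water_t1))
    for series in (mtr_vals, rex_vals, arex_vals):
        assert series[0] < series[1] < series[2]


def test_zspectrum_requires_monotone_offsets():
    with pytest.raises(ValueError):
        ZSpectrum(np.array([1.0, 3.0, 2.0]), np.array([0.5, 0.5, 0.5]))
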