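"""Digital phantom synthesis: geometry, truth maps, noise, conversions."""

import numpy as np
import pytest

from cestmrf import (PhantomSpec, add_noise, default_schedule,
                     glu_conc_to_fraction, glu_fraction_to_conc,
                     make_digital_phantom)


@pytest.fixture(scope="module")
def schedules():
    return {"amide": default_schedule("amide"), "glu": default_schedule("glu")}


@pytest.fixture(scope="module")
def clean_phantom(schedules):
    return make_digital_phantom(PhantomSpec(), schedules, noise_sigma=0.0,
                                seed=0)


class TestGluConversion:
    def test_zero(self):
        assert glu_conc_to_fraction(0.0) == 0.0

    def test_20_mM(self):
        assert glu_conc_to_fraction(20.0) == pytest.approx(5.405405e-4, rel=1e-6)

    def test_round_trip(self):
        conc = np.array([0.0, 5.0, 12.3, 30.0])
        back = glu_fraction_to_conc(glu_conc_to_fraction(conc))
        assert np.allclose(back, conc, atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            glu_conc_to_fraction(-1.0)


def test_spec_has_100_combinations():
    spec = PhantomSpec()
    assert spec.n_rows * spec.n_cols * spec.n_backgrounds == 100


def test_truth_maps_hold_exactly_spec_values(clean_phantom):
    """Each truth map contains the spec's values plus 0 background, nothing
    else, and is constant within every vial."""
    spec = clean_phantom.spec
    amide_vals = set(np.unique(clean_phantom.truth_maps["f_amide"]))
    assert amide_vals == set(spec.amide_fractions) | {0.0}
    glu_vals = set(np.unique(clean_phantom.truth_maps["glu_concentration"]))
    assert glu_vals == set(spec.glu_concentrations) | {0.0}
    labels = clean_phantom.vial_labels
    for v in range(1, labels.max() + 1):
        sel = labels == v
        for name in ("f_amide", "glu_concentration", "f_ss"):
            per_bg = clean_phantom.truth_maps[name][:, sel]
            assert np.all(per_bg == per_bg[:, :1])


def test_100_distinct_parameter_triples(clean_phantom):
    triples = set()
    labels = clean_phantom.vial_labels
    for b in range(4):
        for v in range(1, labels.max() + 1):
            sel = labels == v
            triples.add((
                clean_phantom.truth_maps["f_amide"][b][sel][0],
                clean_phantom.truth_maps["glu_concentration"][b][sel][0],
                clean_phantom.truth_maps["f_ss"][b][sel][0],
            ))
    assert len(triples) == 100


def test_same_vial_pixels_share_trajectories(clean_phantom):
    labels = clean_phantom.vial_labels
    stack = clean_phantom.trajectory_stacks["amide"]
    sel = labels == 13  # center vial
    vial_pix = stack[0][sel]
    assert np.all(vial_pix == vial_pix[:1])
    assert np.all(stack[0][labels == 0] == 0)


def test_degenerate_single_vial_spec():
    spec = PhantomSpec(amide_fractions=[0.004], glu_concentrations=[10.0],
                       mt_fractions=[0.10], image_size=16, vial_radius=3,
                       vial_spacing=8)
    ph = make_digital_phantom(spec, {"amide": default_schedule("amide")},
                              noise_sigma=0.0, seed=0)
    assert ph.vial_labels.max() == 1
    assert ph.truth_maps["f_amide"].shape == (1, 16, 16)


def test_overlapping_vials_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(vial_spacing=6, vial_radius=4).validate()
    with pytest.raises(ValueError):
        PhantomSpec(image_size=32).validate()  # 5x5 at spacing 12 overflows


class TestNoise:
    def test_sigma_zero_is_identity(self):
        traj = np.random.default_rng(0).uniform(0.2, 1.0, (10, 31))
        assert np.array_equal(add_noise(traj, 0.0, seed=1), traj)

    def test_empirical_std_matches_sigma(self):
        traj = np.full((100_000, 2), 1.0)
        traj[:, 0] = 2.0  # M0 = 2 -> noise std = sigma * 2
        noisy = add_noise(traj, 0.01, seed=3)
        assert np.std(noisy[:, 1] - 1.0) == pytest.approx(0.02, rel=0.02)

    def test_seeded_determinism(self):
        traj = np.ones((50, 31))
        a = add_noise(traj, 0.05, seed=9)
        b = add_noise(traj, 0.05, seed=9)
        c = add_noise(traj, 0.05, seed=10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.ones((2, 31)), -0.1, seed=0)


def test_repetition_changes_noise_not_truth(schedules):
    """Regenerating with different seeds alters only the noise realization."""
    a = make_digital_phantom(PhantomSpec(), schedules, noise_sigma=0.01, seed=1)
    b = make_digital_phantom(PhantomSpec(), schedules, noise_sigma=0.01, seed=2)
    for name in a.truth_maps:
        assert np.array_equal(a.truth_maps[name], b.truth_maps[name])
    assert not np.array_equal(a.trajectory_stacks["amide"],
                              b.trajectory_stacks["amide"])


def test_glu_saturation_monotone_in_concentration(clean_phantom):
    """Vial-mean signal in the +3 ppm entries decreases with glutamate
    concentration at fixed amide and MT (noise-free)."""
    sched = default_schedule("glu")
    plus3 = np.array([e.saturation is not None
                      and e.saturation.frequency_offset == 3.0
                      for e in sched.entries])
    stack = clean_phantom.trajectory_stacks["glu"]
    labels = clean_phantom.vial_labels
    # middle amide row (vials 11..15), glutamate increasing along columns
    means = []
    for v in range(11, 16):
        means.append(stack[0][labels == v][:, plus3].mean())
    assert np.all(np.diff(means) < 0)


def test_phantom_round_trip(tmp_path, schedules):
    ph = make_digital_phantom(PhantomSpec(), schedules, noise_sigma=0.01, seed=4)
    ph.save(tmp_path / "ph")
    from cestmrf import PhantomDataset
    back = PhantomDataset.load(tmp_path / "ph")
    assert np.array_equal(back.vial_labels, ph.vial_labels)
    for name in ph.truth_maps:
        assert np.array_equal(back.truth_maps[name], ph.truth_maps[name])
    for name in ph.trajectory_stacks:
        assert np.array_equal(back.trajectory_stacks[name],
                              ph.trajectory_stacks[name])
    assert back.noise_sigma == ph.noise_sigma
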