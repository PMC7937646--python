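"""Circular-statistics unit tests: fits, mixtures, correlation, tests."""

import numpy as np
import pytest
from scipy import stats as st

from retinastats import (
    circular_correlation,
    fit_von_mises,
    fit_von_mises_mixture,
    kuiper_two_sample,
    watson_williams,
)
from retinastats.circular import sample_von_mises_mixture


def vm_orientations(mu_deg, kappa2, n, seed):
    """Orientation sample ([0, 180)) from a doubled-space von Mises."""
    theta2 = st.vonmises.rvs(
        kappa2, loc=np.radians(2 * mu_deg), size=n,
        random_state=np.random.default_rng(seed),
    )
    return (np.degrees(theta2) / 2.0) % 180.0


class TestVonMisesFit:
    def test_recovery_large_sample(self):
        a = vm_orientations(40.0, 6.0, 10000, seed=0)
        fit = fit_von_mises(a)
        assert abs((fit.mu_deg - 40.0 + 90) % 180 - 90) < 2.0
        assert fit.kappa2 == pytest.approx(6.0, rel=0.10)
        # Reporting convention: mu and kappa both halved from doubled space.
        assert fit.kappa == pytest.approx(fit.kappa2 / 2.0)

    def test_uniform_sample_low_concentration(self):
        rng = np.random.default_rng(1)
        fit = fit_von_mises(rng.uniform(0, 180, 5000))
        assert fit.kappa2 < 0.1
        assert fit.rbar < 0.05

    def test_degenerate_single_angle_capped(self):
        fit = fit_von_mises(np.full(100, 42.0))
        assert fit.mu_deg == pytest.approx(42.0)
        assert fit.kappa2 == 500.0

    def test_min_n(self):
        with pytest.raises(ValueError):
            fit_von_mises(np.arange(5.0))


class TestVonMisesMixture:
    def test_recovery_cardinal_modes(self):
        # Spec-level target: means +-3 deg, kappa +-10%, weights +-0.05 at
        # n = 1e4.
        a = sample_von_mises_mixture(
            [0.0, 90.0], [5.0, 5.0], [0.4, 0.6], 10000, seed=2
        )
        mix = fit_von_mises_mixture(a)
        # Match components to targets on the half-circle (a mean near 0 may
        # come out near 180).
        targets = np.array([0.0, 90.0])
        d = np.abs((mix.mus_deg[:, None] - targets[None, :] + 90) % 180 - 90)
        idx = d.argmin(axis=0)
        assert idx[0] != idx[1]
        assert d[idx[0], 0] < 3.0 and d[idx[1], 1] < 3.0
        np.testing.assert_allclose(mix.kappas2[idx], [5.0, 5.0], rtol=0.10)
        np.testing.assert_allclose(mix.weights[idx], [0.4, 0.6], atol=0.05)
        assert not mix.degenerate

    def test_components_sorted_by_mean(self):
        a = sample_von_mises_mixture(
            [120.0, 30.0], [6.0, 6.0], [0.5, 0.5], 4000, seed=3
        )
        mix = fit_von_mises_mixture(a)
        assert mix.mus_deg[0] < mix.mus_deg[1]

    def test_single_mode_degenerates_gracefully(self):
        a = vm_orientations(60.0, 8.0, 4000, seed=4)
        mix = fit_von_mises_mixture(a)
        close = np.abs((mix.mus_deg - 60.0 + 90) % 180 - 90)
        assert close.min() < 3.0
        assert mix.degenerate or mix.weights.max() > 0.5

    def test_sample_range(self):
        a = sample_von_mises_mixture([10.0, 100.0], [4.0, 4.0], [0.5, 0.5], 500, 5)
        assert np.all((a >= 0.0) & (a < 180.0))

    def test_min_n(self):
        with pytest.raises(ValueError):
            fit_von_mises_mixture(np.arange(10.0))


class TestCircularCorrelation:
    def test_perfect_association(self):
        chi = np.arange(0, 360, 45.0)
        res = circular_correlation(
            chi % 180.0, chi, a_axial=True, b_axial=True,
            seed=0, alternative="greater", n_permutations=999,
        )
        assert res.rho == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 360, 30)
        b = (a + rng.normal(0, 20, 30)) % 360
        r1 = circular_correlation(a, b, n_permutations=0).rho
        r2 = circular_correlation((a + 111) % 360, (b + 222) % 360,
                                  n_permutations=0).rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_null_independence(self):
        rng = np.random.default_rng(7)
        res = circular_correlation(
            rng.uniform(0, 360, 500), rng.uniform(0, 360, 500),
            seed=1, n_permutations=499,
        )
        assert abs(res.rho) < 0.1
        assert res.p_value > 0.05

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            circular_correlation([0.0, 90.0], [0.0, 90.0])


class TestWatsonWilliams:
    def test_identical_groups(self):
        a = vm_orientations(30.0, 5.0, 300, seed=8)
        res = watson_williams([a, a.copy()], axial=True)
        assert res.F == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_power_30_degree_separation(self):
        # Two von Mises groups 30 degrees apart (circular space), kappa=5,
        # n=200: detected at p < 0.01 in >= 95% of seeded repetitions.
        hits = 0
        reps = 40
        for s in range(reps):
            g1 = np.degrees(st.vonmises.rvs(
                5.0, loc=0.0, size=200, random_state=np.random.default_rng(2 * s)
            ))
            g2 = np.degrees(st.vonmises.rvs(
                5.0, loc=np.radians(30.0), size=200,
                random_state=np.random.default_rng(2 * s + 1),
            ))
            if watson_williams([g1, g2]).p_value < 0.01:
                hits += 1
        assert hits >= 0.95 * reps

    def test_type_one_error_calibrated(self):
        # Nominal 5% level within [3%, 7%] over 2,000 null simulations.
        rng = np.random.default_rng(9)
        rejections = 0
        n_sim = 2000
        pool = np.degrees(st.vonmises.rvs(4.0, loc=0.0, size=(n_sim, 100),
                                          random_state=rng))
        for row in pool:
            if watson_williams([row[:50], row[50:]]).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_low_concentration_flagged(self):
        rng = np.random.default_rng(10)
        res = watson_williams(
            [rng.uniform(0, 360, 100), rng.uniform(0, 360, 100)]
        )
        assert res.low_concentration

    def test_group_size_minimum(self):
        with pytest.raises(ValueError):
            watson_williams([np.arange(5.0), np.arange(20.0)])


class TestKuiper:
    def test_identical_samples(self):
        a = vm_orientations(45.0, 4.0, 200, seed=11)
        res = kuiper_two_sample(a, a.copy(), axial=True)
        assert res.p_value > 0.9

    def test_power_90_degree_separation(self):
        hits = 0
        reps = 40
        for s in range(reps):
            g1 = np.degrees(st.vonmises.rvs(
                4.0, loc=0.0, size=200, random_state=np.random.default_rng(100 + 2 * s)
            ))
            g2 = np.degrees(st.vonmises.rvs(
                4.0, loc=np.radians(90.0), size=200,
                random_state=np.random.default_rng(101 + 2 * s),
            ))
            if kuiper_two_sample(g1, g2).p_value < 0.01:
                hits += 1
        assert hits >= 0.95 * reps

    def test_rotation_invariance(self):
        a = vm_orientations(20.0, 3.0, 150, seed=12)
        b = vm_orientations(70.0, 3.0, 150, seed=13)
        v1 = kuiper_two_sample(a, b, axial=True).V
        v2 = kuiper_two_sample((a + 40) % 180, (b + 40) % 180, axial=True).V
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_sample_size_minimum(self):
        with pytest.raises(ValueError):
            kuiper_two_sample(np.arange(5.0), np.arange(20.0))
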