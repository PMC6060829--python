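"""The seven uniformity tests: exact cases, oracles, invariances, calibration."""

import math

import numpy as np
import pytest

from circuni import (
    AngleSample,
    TestConfig,
    bogdan_test,
    calibrate_null,
    hermans_rasson_test,
    kuiper_test,
    paired_rejection_rates,
    rao_spacing_test,
    rayleigh_test,
    uniform,
    v_test,
    von_mises,
    watson_test,
)
from circuni import _stats, mode_mixture
from circuni.distributions import draw

TWO_PI = 2.0 * math.pi

ROTATION_INVARIANT = ["kuiper", "watson", "rao", "hermans_rasson", "bogdan"]


def brute_force_kuiper(theta: np.ndarray, grid: int = 200_000) -> float:
    """D+ + D- evaluated on a dense grid of the unit interval."""
    u = np.sort(theta) / TWO_PI
    x = np.linspace(0.0, 1.0, grid, endpoint=False)
    f_right = np.searchsorted(u, x, side="right") / u.size
    f_left = np.searchsorted(u, x, side="left") / u.size
    return float((f_right - x).max() + (x - f_left).max())


class TestRayleigh:
    def test_regular_grid_gives_p_one(self):
        s = AngleSample(TWO_PI * np.arange(12) / 12)
        res = rayleigh_test(s)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_identical_angles_reject_strongly(self):
        res = rayleigh_test(AngleSample([2.0] * 20))
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 1e-6

    def test_small_n_requires_monte_carlo(self):
        with pytest.raises(ValueError):
            rayleigh_test(AngleSample([0.1, 0.2]), method="analytic")
        res = rayleigh_test(AngleSample([0.1, 0.2, 0.3]), method="monte_carlo", mc_reps=999)
        assert res.method == "monte_carlo" and res.mc_reps == 999


class TestVTest:
    def test_concentration_at_mu0(self):
        res = v_test(AngleSample([1.0] * 25), mu0=1.0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value < 1e-6
        assert res.mu0 == pytest.approx(1.0)

    def test_orthogonal_concentration_gives_half(self):
        res = v_test(AngleSample([0.5] * 25), mu0=0.5 + math.pi / 2)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5, abs=0.05)

    def test_mu0_required(self):
        with pytest.raises(ValueError):
            v_test(AngleSample([0.1, 0.2]), mu0=None)

    def test_outpowers_rayleigh_when_direction_correct(self):
        # paired simulation at kappa = 1, n = 15
        rates = paired_rejection_rates(
            [TestConfig("v", mu0=0.0), TestConfig("rayleigh")],
            von_mises(0.0, 1.0), n=15, reps=4000, seed=5,
        )
        assert rates["v_0deg"][0] > rates["rayleigh"][0]


class TestKuiper:
    def test_matches_brute_force_on_random_samples(self, rng):
        for _ in range(5):
            theta = rng.uniform(0, TWO_PI, 20)
            stat = kuiper_test(AngleSample(theta)).statistic
            assert stat == pytest.approx(brute_force_kuiper(theta), abs=1e-4)

    def test_regular_grid_minimises_statistic(self, rng):
        n = 20
        grid_stat = kuiper_test(AngleSample(TWO_PI * np.arange(n) / n)).statistic
        assert grid_stat == pytest.approx(brute_force_kuiper(TWO_PI * np.arange(n) / n), abs=1e-4)
        for _ in range(20):
            other = kuiper_test(AngleSample(rng.uniform(0, TWO_PI, n))).statistic
            assert other >= grid_stat - 1e-12

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            kuiper_test(AngleSample([0.5]))


class TestWatson:
    def test_antipodal_pair_hand_value(self):
        # n = 2 at {a, a+pi}: both centred deviations vanish, U^2 = 1/(12*2)
        res = watson_test(AngleSample([0.3, 0.3 + math.pi]))
        assert res.statistic == pytest.approx(1.0 / 24.0, abs=1e-12)

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            watson_test(AngleSample([0.5]))


class TestRaoSpacing:
    def test_regular_grid_gives_zero(self):
        s = AngleSample(TWO_PI * np.arange(10) / 10)
        res = rao_spacing_test(s, mc_reps=999, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_identical_angles_direct_arithmetic(self):
        # one spacing of 2*pi, nine of zero: U = 2*pi*(1 - 1/10)
        n = 10
        lam = TWO_PI / n
        expected = 0.5 * ((n - 1) * lam + (TWO_PI - lam))
        res = rao_spacing_test(AngleSample([1.0] * n), mc_reps=999, seed=0)
        assert res.statistic == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(TWO_PI * (1 - 1 / n), abs=1e-12)

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            rao_spacing_test(AngleSample([0.1, 0.2, 0.3]))


class TestHermansRasson:
    def test_outpowers_rayleigh_on_symmetric_bimodal(self):
        rates = paired_rejection_rates(
            [TestConfig("hermans_rasson"), TestConfig("rayleigh")],
            mode_mixture(2, "symmetric", 3.0), n=25, reps=1000, seed=6,
        )
        assert rates["hermans_rasson"][0] > 0.5
        assert rates["rayleigh"][0] < 0.15

    def test_calibration_mismatch_rejected(self):
        cal = calibrate_null("hermans_rasson", n=10, reps=999, seed=0)
        with pytest.raises(ValueError, match="does not match"):
            hermans_rasson_test(AngleSample([0.1] * 12), calibration=cal)
        cal2 = calibrate_null("rao", n=12, reps=999, seed=0)
        with pytest.raises(ValueError, match="calibration is for"):
            hermans_rasson_test(AngleSample([0.1] * 12), calibration=cal2)


class TestBogdan:
    def test_selects_first_harmonic_for_moderate_unimodal(self, rng):
        # kappa = 1: higher harmonics are weak, the first dominates
        theta = rng.vonmises(0.0, 1.0, size=(500, 25)) % TWO_PI
        _, dims = _stats.bogdan_statistic(theta)
        assert (dims == 1).mean() > 0.75

    def test_max_dim_validated(self):
        with pytest.raises(ValueError):
            bogdan_test(AngleSample([0.1] * 10), max_dim=0)

    def test_reports_selected_dimension(self):
        res = bogdan_test(AngleSample(np.linspace(0, 1, 25)), mc_reps=999, seed=0)
        assert 1 <= res.extra["selected_dim"] <= res.extra["max_dim"]


@pytest.mark.parametrize("name", ROTATION_INVARIANT)
def test_rotation_invariance_of_statistics(name, rng):
    theta = rng.uniform(0, TWO_PI, 30)
    stat = _stats.statistic_by_name(name)
    base = stat(theta)
    for delta in rng.uniform(0, TWO_PI, 10):
        rotated = (theta + delta) % TWO_PI
        assert abs(stat(rotated) - base) < 1e-9


class TestNullCalibration:
    def test_deterministic_given_seed(self):
        a = calibrate_null("hermans_rasson", 25, reps=999, seed=7)
        b = calibrate_null("hermans_rasson", 25, reps=999, seed=7)
        np.testing.assert_array_equal(a.sorted_stats, b.sorted_stats)

    def test_median_null_statistic_has_p_half(self):
        cal = calibrate_null("rao", 25, reps=999, seed=1)
        med = np.median(cal.sorted_stats)
        assert cal.p_value(med) == pytest.approx(0.5, abs=0.01)

    def test_minimum_reps_enforced(self):
        with pytest.raises(ValueError):
            calibrate_null("rao", 25, reps=500)

    def test_hr_pvalue_stable_across_calibrations(self, rng):
        sample = AngleSample(rng.uniform(0, TWO_PI, 25))
        p1 = hermans_rasson_test(sample, mc_reps=9999, seed=1).p_value
        p2 = hermans_rasson_test(sample, mc_reps=9999, seed=2).p_value
        assert abs(p1 - p2) < 0.02


class TestAnalyticVsMonteCarlo:
    @pytest.mark.parametrize("name", ["rayleigh", "v", "kuiper", "watson"])
    def test_pvalues_agree_on_von_mises_samples(self, name, rng):
        # 200 samples from vM(0, 2) at n = 25; one shared 9,999-rep null table
        n, n_samples, reps = 25, 200, 9999
        cal = calibrate_null(name, n, reps=reps, seed=11)
        theta = draw(von_mises(0.0, 2.0), (n_samples, n), rng)
        stat = _stats.statistic_by_name(name, mu0=0.0)(theta)
        p_an = _stats.analytic_pvalue_by_name(name, stat, n)
        p_mc = cal.p_value(stat)
        band = 3.0 * np.sqrt(p_an * (1 - p_an) / reps) + 0.005
        frac_within = (np.abs(p_mc - p_an) <= band).mean()
        assert frac_within >= 0.95
        assert np.abs(p_mc - p_an).mean() < 0.01


class TestTypeIError:
    """All seven tests hold the nominal level under uniformity."""

    @pytest.mark.parametrize("n", [10, 25, 100])
    def test_rejection_rate_within_band(self, n):
        reps = 10_000
        tests = [
            TestConfig("rayleigh"), TestConfig("v", mu0=0.0), TestConfig("kuiper"),
            TestConfig("watson"), TestConfig("rao"), TestConfig("hermans_rasson"),
            TestConfig("bogdan"),
        ]
        rates = paired_rejection_rates(tests, uniform(), n, reps=reps, seed=n)
        # allowance beyond binomial noise: null-table quantile noise for the
        # Monte-Carlo tests and the O(1/n) bias of the analytic tail series
        # (about +0.001 at n = 10, measured at 100k reps)
        band = 3.0 * math.sqrt(0.05 * 0.95 / reps) + 0.004
        for label, (power, _) in rates.items():
            assert abs(power - 0.05) < band, f"{label} at n={n}: {power}"

    @pytest.mark.parametrize("name", ["rao", "hermans_rasson", "bogdan"])
    def test_null_pvalues_approximately_uniform(self, name, rng):
        n, reps = 25, 10_000
        cal = calibrate_null(name, n, reps=9999, seed=3)
        theta = rng.uniform(0, TWO_PI, (reps, n))
        p = cal.p_value(_stats.statistic_by_name(name)(theta))
        grid = np.sort(p)
        ks = np.abs(grid - (np.arange(1, reps + 1) - 0.5) / reps).max()
        assert ks < 0.02


class TestPowerMonotonicity:
    def test_power_nondecreasing_in_kappa_and_n(self):
        cfgs = [TestConfig("rayleigh"), TestConfig("kuiper"), TestConfig("hermans_rasson")]
        reps = 2000
        slack = 3.0 * math.sqrt(0.25 / reps)
        by_kappa = {
            k: paired_rejection_rates(cfgs, von_mises(0.0, k), 25, reps=reps, seed=8)
            for k in (0.0, 0.75, 1.5, 2.25)
        }
        by_n = {
            n: paired_rejection_rates(cfgs, von_mises(0.0, 1.0), n, reps=reps, seed=9)
            for n in (10, 25, 60)
        }
        for cfg in cfgs:
            kp = [by_kappa[k][cfg.label][0] for k in sorted(by_kappa)]
            np_ = [by_n[n][cfg.label][0] for n in sorted(by_n)]
            assert all(b >= a - slack for a, b in zip(kp, kp[1:])), (cfg.label, kp)
            assert all(b >= a - slack for a, b in zip(np_, np_[1:])), (cfg.label, np_)


def test_doubling_matches_half_distribution_rayleigh(rng):
    # exact 2-fold symmetric data: Rayleigh after doubling equals Rayleigh
    # of the doubled half-sample
    half = rng.vonmises(1.2, 2.0, size=40) % TWO_PI
    sym = np.concatenate([half, half + math.pi]) % TWO_PI
    from circuni import ffold_transform

    r_sym = rayleigh_test(ffold_transform(AngleSample(sym), 2))
    r_half = rayleigh_test(ffold_transform(AngleSample(half), 2))
    assert r_sym.statistic == pytest.approx(r_half.statistic, abs=1e-12)
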