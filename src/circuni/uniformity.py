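"""Seven tests of circular uniformity with a shared Monte-Carlo backend.

The null hypothesis throughout is that the sample was drawn from the
uniform distribution on the circle.  Four tests have trustworthy analytic
p-value approximations (Rayleigh, V, Kuiper, Watson); Rao's spacing test
defaults to Monte-Carlo (published tables are coarse), and the
Hermans–Rasson and adaptive smooth (Bogdan) tests have no closed-form null
at all, so they are always calibrated by simulation.

The Monte-Carlo null depends only on the sample size, so a
:class:`NullCalibration` computed once can be reused across thousands of
samples — this is what makes large power sweeps affordable.  Empirical
p-values use the (1 + #{null ≥ observed}) / (reps + 1) convention, which
never returns 0 and yields an exactly valid test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _stats
from ._stats import ALL_TESTS, HAS_ANALYTIC, MC_ONLY
from .sample import TWO_PI, AngleSample

__all__ = [
    "TestResult",
    "NullCalibration",
    "calibrate_null",
    "rayleigh_test",
    "v_test",
    "kuiper_test",
    "watson_test",
    "rao_spacing_test",
    "hermans_rasson_test",
    "bogdan_test",
    "ALL_TESTS",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single uniformity test."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    method: str                      # "analytic" | "monte_carlo"
    mc_reps: Optional[int] = None
    mu0: Optional[float] = None      # V-test only, radians
    f_used: Optional[int] = None     # records an f-fold pre-transform
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.method == "monte_carlo" and self.mc_reps is None:
            raise ValueError("monte_carlo result must record mc_reps")


@dataclass(frozen=True)
class NullCalibration:
    """Sorted null statistics of one test at one sample size.

    Valid for any sample of the same n because the null law of every
    statistic here depends only on n under uniformity.
    """

    test_name: str
    n: int
    reps: int
    seed: Optional[int]
    sorted_stats: np.ndarray
    max_dim: Optional[int] = None  # Bogdan only

    def __post_init__(self) -> None:
        arr = np.sort(np.asarray(self.sorted_stats, dtype=float))
        object.__setattr__(self, "sorted_stats", arr)
        arr.setflags(write=False)
        if arr.size != self.reps:
            raise ValueError("calibration length disagrees with reps")

    def p_value(self, observed: float | np.ndarray) -> np.ndarray | float:
        """Empirical upper-tail p: (1 + #{null ≥ obs}) / (reps + 1)."""
        obs = np.asarray(observed, dtype=float)
        n_ge = self.reps - np.searchsorted(self.sorted_stats, obs, side="left")
        p = (1.0 + n_ge) / (self.reps + 1.0)
        return float(p) if np.isscalar(observed) else p


def calibrate_null(
    test_name: str,
    n: int,
    reps: int = 9999,
    seed: int | None = 0,
    max_dim: int = _stats.BOGDAN_MAX_DIM,
) -> NullCalibration:
    """Simulate the null distribution of a test statistic at sample size n.

    Deterministic given ``seed``.  Requires reps ≥ 999 so that the empirical
    p-value has resolution finer than conventional α levels.
    """
    if test_name not in ALL_TESTS:
        raise ValueError(f"unknown test: {test_name!r}")
    if reps < 999:
        raise ValueError("need at least 999 calibration replicates")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, TWO_PI, size=(reps, n))
    stat_fn = _stats.statistic_by_name(test_name, max_dim=max_dim)
    stats = stat_fn(theta)
    return NullCalibration(
        test_name,
        n,
        reps,
        seed,
        stats,
        max_dim=max_dim if test_name == "bogdan" else None,
    )


def _check_calibration(cal: NullCalibration, test_name: str, n: int) -> None:
    if cal.test_name != test_name:
        raise ValueError(f"calibration is for {cal.test_name!r}, not {test_name!r}")
    if cal.n != n:
        raise ValueError(f"calibration n = {cal.n} does not match sample n = {n}")


def _mc_result(
    test_name: str,
    stat: float,
    sample: AngleSample,
    calibration: NullCalibration | None,
    mc_reps: int,
    seed: int | None,
    max_dim: int = _stats.BOGDAN_MAX_DIM,
    **fields,
) -> TestResult:
    if calibration is None:
        calibration = calibrate_null(test_name, sample.n, reps=mc_reps, seed=seed, max_dim=max_dim)
    _check_calibration(calibration, test_name, sample.n)
    p = float(calibration.p_value(stat))
    return TestResult(
        test_name, float(stat), p, sample.n, "monte_carlo", mc_reps=calibration.reps, **fields
    )


def rayleigh_test(
    sample: AngleSample,
    method: str = "analytic",
    calibration: NullCalibration | None = None,
    mc_reps: int = 9999,
    seed: int | None = 0,
) -> TestResult:
    """Rayleigh test: rejects uniformity for large mean resultant length r.

    The most powerful rotation-invariant test against a von Mises
    alternative, but nearly blind to symmetric multimodal departures.
    The reported statistic is r; significance derives from R = n·r.
    """
    r = float(_stats.resultant_length(sample.values))
    if method == "analytic":
        if sample.n < 4:
            raise ValueError("analytic Rayleigh approximation needs n >= 4")
        p = float(_stats.rayleigh_pvalue(r, sample.n))
        return TestResult("rayleigh", r, p, sample.n, "analytic")
    return _mc_result("rayleigh", r, sample, calibration, mc_reps, seed)


def v_test(
    sample: AngleSample,
    mu0: float,
    method: str = "analytic",
    calibration: NullCalibration | None = None,
    mc_reps: int = 9999,
    seed: int | None = 0,
) -> TestResult:
    """V-test: Rayleigh variant with a pre-specified mean direction μ0.

    One-sided; gains power over Rayleigh when the true mean is near μ0.
    μ0 must be fixed *before* inspecting the data — choosing it afterwards
    inflates the type-I error.  A significant V-test alone does not show
    concentration *at* μ0; pair it with a confidence interval for the mean
    direction (:func:`circuni.sample.mean_direction_ci`).
    """
    if mu0 is None:
        raise ValueError("v_test requires a pre-specified mean direction mu0")
    mu0 = float(mu0) % TWO_PI
    v = float(_stats.v_statistic(sample.values, mu0))
    u = v * np.sqrt(2.0 * sample.n)
    if method == "analytic":
        p = float(_stats.v_pvalue(v, sample.n))
        return TestResult("v", v, p, sample.n, "analytic", mu0=mu0, extra={"u": float(u)})
    # rotation invariance of the null lets one calibration serve any mu0
    if calibration is None:
        calibration = calibrate_null("v", sample.n, reps=mc_reps, seed=seed)
    _check_calibration(calibration, "v", sample.n)
    p = float(calibration.p_value(v))
    return TestResult(
        "v", v, p, sample.n, "monte_carlo", mc_reps=calibration.reps, mu0=mu0,
        extra={"u": float(u)},
    )


def kuiper_test(
    sample: AngleSample,
    method: str = "analytic",
    calibration: NullCalibration | None = None,
    mc_reps: int = 9999,
    seed: int | None = 0,
) -> TestResult:
    """Kuiper's V_n test — the circle-invariant analogue of Kolmogorov–Smirnov."""
    if sample.n < 2:
        raise ValueError("kuiper_test needs n >= 2")
    v = float(_stats.kuiper_statistic(sample.values))
    if method == "analytic":
        p = float(_stats.kuiper_pvalue(v, sample.n))
        return TestResult("kuiper", v, p, sample.n, "analytic")
    return _mc_result("kuiper", v, sample, calibration, mc_reps, seed)


def watson_test(
    sample: AngleSample,
    method: str = "analytic",
    calibration: NullCalibration | None = None,
    mc_reps: int = 9999,
    seed: int | None = 0,
) -> TestResult:
    """Watson's U² test — the rotation-invariant Cramér–von Mises statistic."""
    if sample.n < 2:
        raise ValueError("watson_test needs n >= 2")
    u2 = float(_stats.watson_statistic(sample.values))
    if method == "analytic":
        p = float(_stats.watson_pvalue(u2, sample.n))
        return TestResult("watson", u2, p, sample.n, "analytic")
    return _mc_result("watson", u2, sample, calibration, mc_reps, seed)


def rao_spacing_test(
    sample: AngleSample,
    calibration: NullCalibration | None = None,
    mc_reps: int = 9999,
    seed: int | None = 0,
) -> TestResult:
    """Rao's spacing test: U = ½ Σ |T_i − 2π/n| over successive arc gaps.

    Sensitive to any clumping of the spacings, which gives it unusual
    robustness against multimodal alternatives.  p-values are Monte-Carlo;
    published critical-value tables exist but are coarse.  Ties (zero
    spacings) are legal.
    """
    if sample.n < 4:
        raise ValueError("rao_spacing_test needs n >= 4")
    u = float(_stats.rao_statistic(sample.values))
    return _mc_result("rao", u, sample, calibration, mc_reps, seed)


def hermans_rasson_test(
    sample: AngleSample,
    calibration: NullCalibration | None = None,
    mc_reps: int = 9999,
    seed: int | None = 0,
) -> TestResult:
    """Hermans–Rasson test: a pairwise-difference statistic with broad power.

    T = (1/n) Σ_i Σ_j h(θ_i − θ_j) with the rotation-invariant kernel
    h(d) = | |d| − π | − π/2 − 2.895·(|sin d| − 2/π).  Designed to retain
    power against multimodal departures where the Rayleigh test fails;
    the recommended default when the shape of the alternative is unknown.
    No closed-form null: p-values are always Monte-Carlo.
    """
    if sample.n < 4:
        raise ValueError("hermans_rasson_test needs n >= 4")
    t = float(_stats.hermans_rasson_statistic(sample.values))
    return _mc_result("hermans_rasson", t, sample, calibration, mc_reps, seed)


def bogdan_test(
    sample: AngleSample,
    calibration: NullCalibration | None = None,
    max_dim: int = _stats.BOGDAN_MAX_DIM,
    mc_reps: int = 9999,
    seed: int | None = 0,
) -> TestResult:
    """Data-driven smooth test: Fourier scores with Schwarz-rule selection.

    Accumulates squared Fourier scores N_k = Σ_{j≤k}(c_j² + s_j²) and
    selects the dimension maximising N_k − 2k·log n; the statistic is N at
    the selected dimension.  The same selection runs inside every null
    draw of the calibration — skipping that makes the test anticonservative.
    """
    if sample.n < 5:
        raise ValueError("bogdan_test needs n >= 5")
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    stat, dim = _stats.bogdan_statistic(sample.values, max_dim)
    result = _mc_result(
        "bogdan", float(stat), sample, calibration, mc_reps, seed, max_dim=max_dim
    )
    result.extra["selected_dim"] = int(dim)
    result.extra["max_dim"] = max_dim
    return result
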