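"""Monte-Carlo estimation of type-I error and statistical power.

The engine draws ``reps`` samples of size n from a generating distribution,
applies one or more test configurations to the *same* samples (pairing the
tests cuts the variance of between-test comparisons) and reports the
proportion of p-values below α together with its binomial standard error
√(p̂(1−p̂)/reps).

A scenario is a grid: one swept generator parameter × sample sizes × test
configurations.  Per-cell random streams are derived from the master seed
and the cell coordinates, so any cell can be re-run in isolation and cells
are mutually independent.  Null-calibration tables are built once per
(test, n) and shared across the whole grid.

:func:`reference_scenario` returns the pre-registered sweeps of the
simulation study this package reproduces (type-I error across eight sample
sizes; unimodal von Mises / wrapped Cauchy / skew-normal power; bimodal and
multimodal mixtures swept over concentration, mode separation, relative
weight and per-mode concentration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _stats, distributions as dist
from .sample import TWO_PI
from .uniformity import NullCalibration, calibrate_null

__all__ = [
    "TestConfig",
    "ScenarioSpec",
    "PowerResult",
    "estimate_rejection_rate",
    "rejection_matrix",
    "paired_rejection_rates",
    "run_scenario",
    "reference_scenario",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class TestConfig:
    """One test as applied in a simulation: name plus its options.

    ``mu0`` (radians) applies to the V-test; ``ffold`` applies an f-fold
    pre-transform before the test (the "Rayleigh (2×)" trick); ``method``
    is "auto" (analytic where available, Monte-Carlo otherwise),
    "analytic" or "monte_carlo".
    """

    name: str
    mu0: Optional[float] = None
    ffold: Optional[int] = None
    max_dim: int = _stats.BOGDAN_MAX_DIM
    method: str = "auto"

    def __post_init__(self) -> None:
        if self.name not in _stats.ALL_TESTS:
            raise ValueError(f"unknown test: {self.name!r}")
        if self.name == "v" and self.mu0 is None:
            raise ValueError("V-test config requires mu0")
        if self.ffold is not None and self.ffold < 1:
            raise ValueError("ffold must be a positive integer")
        if self.method not in ("auto", "analytic", "monte_carlo"):
            raise ValueError(f"unknown method: {self.method!r}")
        if self.method == "analytic" and self.name in _stats.MC_ONLY:
            raise ValueError(f"{self.name} has no analytic p-value")

    @property
    def uses_mc(self) -> bool:
        if self.method == "monte_carlo":
            return True
        return self.method == "auto" and self.name in _stats.MC_ONLY

    @property
    def label(self) -> str:
        parts = [self.name]
        if self.name == "v" and self.mu0 is not None:
            parts.append(f"{round(math.degrees(self.mu0))}deg")
        if self.ffold is not None and self.ffold != 1:
            parts.append(f"{self.ffold}x")
        return "_".join(parts)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation experiment: generator grid × tests × sample sizes.

    ``generator`` is a config mapping (see :func:`build_generator`); if
    ``sweep_param`` is set, that key is overwritten by each value of
    ``sweep_values`` in turn.  Angular entries of the mapping are radians.
    """

    name: str
    generator: Mapping
    sweep_param: Optional[str]
    sweep_values: tuple[float, ...]
    sample_sizes: tuple[int, ...]
    tests: tuple[TestConfig, ...]
    reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    mc_null_reps: int = 9_999

    def __post_init__(self) -> None:
        if self.reps < 100:
            raise ValueError("reps must be >= 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        sweep = tuple(float(v) for v in self.sweep_values)
        if not sweep:
            raise ValueError("sweep_values must be non-empty")
        if any(b <= a for a, b in zip(sweep, sweep[1:])):
            raise ValueError("sweep_values must be strictly increasing")
        object.__setattr__(self, "sweep_values", sweep)
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in self.sample_sizes))
        object.__setattr__(self, "tests", tuple(self.tests))
        if not self.tests or not self.sample_sizes:
            raise ValueError("need at least one test and one sample size")


#: result grid: one row per (sweep value, n, test configuration)
PowerResult = pd.DataFrame

_RESULT_COLUMNS = [
    "scenario", "test", "n", "sweep_name", "sweep_value",
    "rejections", "reps", "power", "se",
]


def build_generator(
    config: Mapping, sweep_param: str | None = None, value: float | None = None
) -> dist.DistributionSpec:
    """Materialise a distribution spec from a config mapping.

    Recognised ``kind`` values: ``uniform``, ``von_mises``,
    ``wrapped_cauchy``, ``wrapped_skew_normal``, ``mixture`` (explicit
    components), ``mode_mixture`` (standard layouts) and ``bimodal``
    (two von Mises modes parameterised by separation ``delta``, per-mode
    ``kappa1``/``kappa2`` and first-mode ``weight1``).  All angles radians.
    """
    cfg = dict(config)
    if sweep_param is not None:
        if value is None:
            raise ValueError("sweep value required when sweep_param is set")
        cfg[sweep_param] = float(value)
    kind = cfg.pop("kind")
    if kind == "uniform":
        return dist.uniform()
    if kind == "von_mises":
        return dist.von_mises(cfg.get("mu", 0.0), cfg["kappa"])
    if kind == "wrapped_cauchy":
        return dist.wrapped_cauchy(cfg.get("mu", 0.0), cfg["rho"])
    if kind == "wrapped_skew_normal":
        return dist.wrapped_skew_normal(
            cfg.get("epsilon", 0.0), cfg["omega"], cfg.get("alpha_shape", 30.0)
        )
    if kind == "mixture":
        return dist.MixtureSpec(tuple(cfg["components"]))
    if kind == "mode_mixture":
        return dist.mode_mixture(int(cfg["n_modes"]), cfg["placement"], cfg["kappa"])
    if kind == "bimodal":
        mu1 = cfg.get("mu1", 0.0)
        delta = cfg.get("delta", math.pi)
        w1 = cfg.get("weight1", 0.5)
        k1 = cfg.get("kappa1", 3.0)
        k2 = cfg.get("kappa2", k1)
        if not 0.0 < w1 < 1.0:
            raise ValueError("weight1 must be in (0, 1)")
        return dist.MixtureSpec(((w1, mu1, k1), (1.0 - w1, mu1 + delta, k2)))
    raise ValueError(f"unknown generator kind: {kind!r}")


# ---------------------------------------------------------------------------
# rejection machinery

def _rejections(
    theta: np.ndarray,
    cfg: TestConfig,
    alpha: float,
    calibrations: Mapping[tuple[str, int], NullCalibration],
) -> np.ndarray:
    """Boolean rejection vector for one test config over a (reps, n) batch."""
    if cfg.ffold is not None and cfg.ffold != 1:
        theta = np.mod(cfg.ffold * theta, TWO_PI)
    n = theta.shape[-1]
    stat = _stats.statistic_by_name(cfg.name, mu0=cfg.mu0 or 0.0, max_dim=cfg.max_dim)(theta)
    if cfg.uses_mc:
        cal = calibrations[(cfg.name, n)]
        return cal.p_value(stat) < alpha
    return _stats.analytic_pvalue_by_name(cfg.name, stat, n) < alpha


def _cell_rng(seed: int | None, i: int, j: int) -> np.random.Generator:
    # stream for grid cell (sweep index i, sample-size index j)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, i, j)))


def _needed_calibrations(
    tests: Sequence[TestConfig],
    sample_sizes: Sequence[int],
    reps: int,
    seed: int | None,
) -> dict[tuple[str, int], NullCalibration]:
    keys = sorted(
        {(t.name, n, t.max_dim) for t in tests if t.uses_mc for n in sample_sizes}
    )
    out: dict[tuple[str, int], NullCalibration] = {}
    for k, (name, n, max_dim) in enumerate(keys):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(0, k))
        cal_seed = int(child.generate_state(1)[0] % (2**31))
        out[(name, n)] = calibrate_null(name, n, reps=reps, seed=cal_seed, max_dim=max_dim)
    return out


def rejection_matrix(
    tests: Sequence[TestConfig],
    generator: dist.DistributionSpec,
    n: int,
    reps: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = 0,
    calibrations: Mapping[tuple[str, int], NullCalibration] | None = None,
    mc_null_reps: int = 9_999,
) -> dict[str, np.ndarray]:
    """Per-replicate rejection indicators for several tests on shared samples.

    Returns ``{config.label: bool array of length reps}``.  This is the
    primitive behind :func:`paired_rejection_rates`; keep the indicators when
    you need the standard error of a *difference* in power between tests.
    """
    if calibrations is None:
        calibrations = _needed_calibrations(tests, [n], mc_null_reps, seed)
    theta = dist.draw(generator, (reps, n), _cell_rng(seed, 0, 0))
    return {cfg.label: _rejections(theta, cfg, alpha, calibrations) for cfg in tests}


def paired_rejection_rates(
    tests: Sequence[TestConfig],
    generator: dist.DistributionSpec,
    n: int,
    reps: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = 0,
    calibrations: Mapping[tuple[str, int], NullCalibration] | None = None,
    mc_null_reps: int = 9_999,
) -> dict[str, tuple[float, float]]:
    """Rejection proportion and SE for several tests on the SAME samples.

    Returns ``{config.label: (power, se)}``.  Sharing the simulated samples
    across tests makes between-test power differences far less noisy than
    independent runs of the same size.
    """
    matrix = rejection_matrix(
        tests, generator, n, reps=reps, alpha=alpha, seed=seed,
        calibrations=calibrations, mc_null_reps=mc_null_reps,
    )
    out: dict[str, tuple[float, float]] = {}
    for label, rej in matrix.items():
        p_hat = float(rej.mean())
        out[label] = (p_hat, math.sqrt(p_hat * (1.0 - p_hat) / reps))
    return out


def estimate_rejection_rate(
    test: TestConfig,
    generator: dist.DistributionSpec,
    n: int,
    reps: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = 0,
    calibrations: Mapping[tuple[str, int], NullCalibration] | None = None,
    mc_null_reps: int = 9_999,
) -> tuple[float, float]:
    """Proportion of ``reps`` samples rejected at level α, with its SE.

    Deterministic given ``seed``; under the uniform generator this estimates
    the type-I error, under any other generator the power.
    """
    rates = paired_rejection_rates(
        [test], generator, n, reps=reps, alpha=alpha, seed=seed,
        calibrations=calibrations, mc_null_reps=mc_null_reps,
    )
    return rates[test.label]


def run_scenario(spec: ScenarioSpec, reps: int | None = None) -> PowerResult:
    """Evaluate the full grid of a scenario; returns a tidy DataFrame.

    Per-cell seeds derive from (master seed, sweep index, n index) so cells
    are independent and individually reproducible; ``reps`` overrides the
    scenario's replication count (e.g. for quick looks at reduced scale).
    """
    reps = spec.reps if reps is None else int(reps)
    calibrations = _needed_calibrations(
        spec.tests, spec.sample_sizes, spec.mc_null_reps, spec.seed
    )
    rows = []
    for i, val in enumerate(spec.sweep_values):
        generator = build_generator(spec.generator, spec.sweep_param, val)
        for j, n in enumerate(spec.sample_sizes):
            theta = dist.draw(generator, (reps, n), _cell_rng(spec.seed, i, j))
            for cfg in spec.tests:
                rej = _rejections(theta, cfg, spec.alpha, calibrations)
                k = int(rej.sum())
                p_hat = k / reps
                rows.append({
                    "scenario": spec.name,
                    "test": cfg.label,
                    "n": n,
                    "sweep_name": spec.sweep_param or "none",
                    "sweep_value": val,
                    "rejections": k,
                    "reps": reps,
                    "power": p_hat,
                    "se": math.sqrt(p_hat * (1.0 - p_hat) / reps),
                })
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# the pre-registered scenario catalogue

def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    k = int(round((stop - start) / step))
    return tuple(round(start + i * step, 10) for i in range(k + 1))

_SEVEN = (
    TestConfig("rayleigh"),
    TestConfig("v", mu0=0.0),
    TestConfig("kuiper"),
    TestConfig("watson"),
    TestConfig("rao"),
    TestConfig("hermans_rasson"),
    TestConfig("bogdan"),
)

_UNIMODAL_TESTS = (
    TestConfig("rayleigh"),
    TestConfig("kuiper"),
    TestConfig("watson"),
    TestConfig("rao"),
    TestConfig("v", mu0=0.0),
    TestConfig("v", mu0=math.radians(20.0)),
    TestConfig("v", mu0=math.radians(45.0)),
)

_MULTIMODAL_TESTS = (
    TestConfig("rayleigh"),
    TestConfig("kuiper"),
    TestConfig("watson"),
    TestConfig("rao"),
    TestConfig("hermans_rasson"),
    TestConfig("bogdan"),
)


def _catalogue() -> dict[str, ScenarioSpec]:
    cat: dict[str, ScenarioSpec] = {}

    cat["type1_uniform"] = ScenarioSpec(
        name="type1_uniform",
        generator={"kind": "uniform"},
        sweep_param=None,
        sweep_values=(0.0,),
        sample_sizes=(10, 15, 20, 25, 30, 40, 80, 100),
        tests=_SEVEN,
        reps=100_000,
    )

    # unimodal power sweeps; concentration/dispersion grids bracket the
    # plotted ranges (conventions, documented in the methods note)
    cat["unimodal_von_mises"] = ScenarioSpec(
        name="unimodal_von_mises",
        generator={"kind": "von_mises", "mu": 0.0},
        sweep_param="kappa",
        sweep_values=_grid(0.0, 4.0, 0.5),
        sample_sizes=(15, 25, 40, 100),
        tests=_UNIMODAL_TESTS,
    )
    cat["unimodal_wrapped_cauchy"] = ScenarioSpec(
        name="unimodal_wrapped_cauchy",
        generator={"kind": "wrapped_cauchy", "mu": 0.0},
        sweep_param="rho",
        sweep_values=_grid(0.0, 0.9, 0.1),
        sample_sizes=(15, 25, 40, 100),
        tests=_UNIMODAL_TESTS,
    )
    cat["unimodal_skew_normal"] = ScenarioSpec(
        name="unimodal_skew_normal",
        generator={"kind": "wrapped_skew_normal", "epsilon": 0.0, "alpha_shape": 30.0},
        sweep_param="omega",
        sweep_values=_grid(0.5, 5.0, 0.5),
        sample_sizes=(15, 25, 40, 100),
        tests=_UNIMODAL_TESTS,
    )

    kappa_grid = _grid(0.0, 6.0, 0.1)
    bimodal_tests = _MULTIMODAL_TESTS + (TestConfig("rayleigh", ffold=2),)
    cat["bimodal_symmetric"] = ScenarioSpec(
        name="bimodal_symmetric",
        generator={"kind": "mode_mixture", "n_modes": 2, "placement": "symmetric"},
        sweep_param="kappa",
        sweep_values=kappa_grid,
        sample_sizes=(25,),
        tests=bimodal_tests,
    )
    cat["bimodal_asymmetric"] = ScenarioSpec(
        name="bimodal_asymmetric",
        generator={"kind": "mode_mixture", "n_modes": 2, "placement": "asymmetric"},
        sweep_param="kappa",
        sweep_values=kappa_grid,
        sample_sizes=(25,),
        tests=_MULTIMODAL_TESTS,
    )
    for f in (3, 4, 5, 6):
        for placement in ("symmetric", "asymmetric"):
            tests = _MULTIMODAL_TESTS
            if placement == "symmetric":
                tests = tests + (TestConfig("rayleigh", ffold=f),)
            name = f"multimodal_f{f}_{placement}"
            cat[name] = ScenarioSpec(
                name=name,
                generator={"kind": "mode_mixture", "n_modes": f, "placement": placement},
                sweep_param="kappa",
                sweep_values=kappa_grid,
                sample_sizes=(25,),
                tests=tests,
            )

    # mode-separation sweep (Δ in degrees 0..180, 10° steps)
    cat["bimodal_delta"] = ScenarioSpec(
        name="bimodal_delta",
        generator={"kind": "bimodal", "mu1": 0.0, "kappa1": 3.0, "kappa2": 3.0},
        sweep_param="delta",
        sweep_values=tuple(math.radians(d) for d in range(0, 181, 10)),
        sample_sizes=(15, 25, 40, 100),
        tests=_MULTIMODAL_TESTS,
    )
    # second-mode concentration sweep, first mode fixed at kappa = 3
    cat["bimodal_kappa2"] = ScenarioSpec(
        name="bimodal_kappa2",
        generator={"kind": "bimodal", "mu1": 0.0, "delta": math.pi, "kappa1": 3.0},
        sweep_param="kappa2",
        sweep_values=kappa_grid,
        sample_sizes=(25,),
        tests=_MULTIMODAL_TESTS,
    )
    cat["bimodal_kappa2_asymmetric"] = ScenarioSpec(
        name="bimodal_kappa2_asymmetric",
        generator={"kind": "bimodal", "mu1": 0.0, "delta": math.pi / 2.0, "kappa1": 3.0},
        sweep_param="kappa2",
        sweep_values=kappa_grid,
        sample_sizes=(25,),
        tests=_MULTIMODAL_TESTS,
    )
    # relative-weight sweeps at kappa = 2 and 3 (equal weight = 0.5)
    for kap in (2.0, 3.0):
        for placement, delta in (("symmetric", math.pi), ("asymmetric", math.pi / 2.0)):
            name = f"bimodal_weights_kappa{int(kap)}"
            if placement == "asymmetric":
                name += "_asymmetric"
            cat[name] = ScenarioSpec(
                name=name,
                generator={
                    "kind": "bimodal", "mu1": 0.0, "delta": delta,
                    "kappa1": kap, "kappa2": kap,
                },
                sweep_param="weight1",
                sweep_values=_grid(0.05, 0.5, 0.05),
                sample_sizes=(25,),
                tests=_MULTIMODAL_TESTS,
            )
    return cat


SCENARIO_NAMES = tuple(sorted(_catalogue()))


def reference_scenario(name: str, seed: int = 0, reps: int | None = None) -> ScenarioSpec:
    """Return a pre-registered scenario by name (see :data:`SCENARIO_NAMES`)."""
    cat = _catalogue()
    if name not in cat:
        raise ValueError(f"unknown scenario {name!r}; known: {', '.join(SCENARIO_NAMES)}")
    spec = cat[name]
    spec = replace(spec, seed=seed)
    if reps is not None:
        spec = replace(spec, reps=int(reps))
    return spec
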