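"""Circular distributions used in the simulation study: samplers and densities.

Families
--------
uniform
    The null model: constant density 1/2π.
von Mises
    Symmetric unimodal law with mean ``mu`` and concentration ``kappa``;
    kappa = 0 degenerates to uniform.  Sampled by the Best–Fisher rejection
    algorithm (numpy's generator).
wrapped Cauchy
    Symmetric unimodal law with concentration ``rho`` in [0, 1); sharper
    peaked than von Mises at equal dispersion.  Sampled by drawing a linear
    Cauchy with scale −ln ρ and wrapping mod 2π.
wrapped skew-normal
    The linear skew-normal(ε, ω, α) wrapped onto the circle; α ≠ 0 makes it
    asymmetric.  Dispersion grows with ω, so power *decreases* in ω.
von Mises mixtures
    Finite mixtures of von Mises components — the multimodal alternatives.

Densities exist mainly as quadrature oracles for validating the samplers and
for plotting; sampling is the hot path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .sample import TWO_PI, AngleSample

_FAMILIES = ("uniform", "von_mises", "wrapped_cauchy", "wrapped_skew_normal")


@dataclass(frozen=True)
class UnimodalSpec:
    """Declarative description of a unimodal circular law.

    Exactly the parameters of the declared family may be set; the factory
    helpers (:func:`uniform`, :func:`von_mises`, :func:`wrapped_cauchy`,
    :func:`wrapped_skew_normal`) are the intended constructors.
    """

    family: str
    mu: float | None = None           # von_mises, wrapped_cauchy
    kappa: float | None = None        # von_mises, >= 0
    rho: float | None = None          # wrapped_cauchy, in [0, 1)
    epsilon: float | None = None      # skew-normal location, radians
    omega: float | None = None        # skew-normal dispersion, > 0
    alpha_shape: float | None = None  # skew-normal shape

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family: {self.family!r}")
        required = {
            "uniform": (),
            "von_mises": ("mu", "kappa"),
            "wrapped_cauchy": ("mu", "rho"),
            "wrapped_skew_normal": ("epsilon", "omega", "alpha_shape"),
        }[self.family]
        for name in ("mu", "kappa", "rho", "epsilon", "omega", "alpha_shape"):
            val = getattr(self, name)
            if name in required and val is None:
                raise ValueError(f"{self.family} requires parameter {name}")
            if name not in required and val is not None:
                raise ValueError(f"{self.family} does not take parameter {name}")
        if self.kappa is not None and self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.rho is not None and not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.omega is not None and self.omega <= 0:
            raise ValueError("omega must be > 0")


def uniform() -> UnimodalSpec:
    return UnimodalSpec("uniform")


def von_mises(mu: float, kappa: float) -> UnimodalSpec:
    return UnimodalSpec("von_mises", mu=float(mu), kappa=float(kappa))


def wrapped_cauchy(mu: float, rho: float) -> UnimodalSpec:
    return UnimodalSpec("wrapped_cauchy", mu=float(mu), rho=float(rho))


def wrapped_skew_normal(epsilon: float, omega: float, alpha_shape: float) -> UnimodalSpec:
    return UnimodalSpec(
        "wrapped_skew_normal",
        epsilon=float(epsilon),
        omega=float(omega),
        alpha_shape=float(alpha_shape),
    )


@dataclass(frozen=True)
class MixtureSpec:
    """Finite von Mises mixture: components are (weight, mu, kappa) triples.

    Weights are normalised on construction and must be strictly positive.
    """

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(w), float(m), float(k)) for (w, m, k) in self.components)
        if not comps:
            raise ValueError("mixture needs at least one component")
        total = sum(w for w, _, _ in comps)
        if total <= 0 or any(w <= 0 for w, _, _ in comps):
            raise ValueError("mixture weights must be positive")
        if any(k < 0 for _, _, k in comps):
            raise ValueError("component kappa must be >= 0")
        comps = tuple((w / total, m, k) for (w, m, k) in comps)
        assert abs(sum(w for w, _, _ in comps) - 1.0) < 1e-12
        object.__setattr__(self, "components", comps)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _, _ in self.components])

    @property
    def mus(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.components])

    @property
    def kappas(self) -> np.ndarray:
        return np.array([k for _, _, k in self.components])


DistributionSpec = UnimodalSpec | MixtureSpec


def mode_mixture(n_modes: int, placement: str, kappa: float) -> MixtureSpec:
    """Equal-weight von Mises mixture with a standard mode layout.

    ``placement="symmetric"`` spaces the f modes evenly around the full
    circle (f-fold rotational symmetry): 360°·k/f.  ``"asymmetric"`` breaks
    that symmetry: two modes sit at 0° and 90°, and for f ≥ 3 the modes are
    packed into the half-circle at 180°/(f−1) increments (f = 4 gives
    0°, 60°, 120°, 180°).
    """
    if not 2 <= n_modes <= 6:
        raise ValueError("n_modes must be between 2 and 6")
    if placement == "symmetric":
        mus = TWO_PI * np.arange(n_modes) / n_modes
    elif placement == "asymmetric":
        if n_modes == 2:
            mus = np.array([0.0, math.pi / 2.0])
        else:
            mus = math.pi / (n_modes - 1) * np.arange(n_modes)
    else:
        raise ValueError(f"unknown placement: {placement!r}")
    w = 1.0 / n_modes
    return MixtureSpec(tuple((w, float(m), float(kappa)) for m in mus))


def draw(spec: DistributionSpec, size: int | tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Draw angles from ``spec``; returns an array of the requested shape.

    All samplers are exact (no discretisation): Best–Fisher rejection for
    von Mises, wrap of a closed-form linear Cauchy for wrapped Cauchy, wrap
    of scipy's skew-normal sampler for the skew family.
    """
    if isinstance(spec, MixtureSpec):
        idx = rng.choice(len(spec.components), size=size, p=spec.weights)
        return np.mod(rng.vonmises(spec.mus[idx], spec.kappas[idx]), TWO_PI)
    if spec.family == "uniform":
        return rng.uniform(0.0, TWO_PI, size=size)
    if spec.family == "von_mises":
        if spec.kappa == 0.0:
            return rng.uniform(0.0, TWO_PI, size=size)
        return np.mod(rng.vonmises(spec.mu, spec.kappa, size=size), TWO_PI)
    if spec.family == "wrapped_cauchy":
        if spec.rho == 0.0:
            return rng.uniform(0.0, TWO_PI, size=size)
        gamma = -math.log(spec.rho)
        return np.mod(spec.mu + gamma * rng.standard_cauchy(size=size), TWO_PI)
    # wrapped skew-normal
    lin = stats.skewnorm.rvs(
        spec.alpha_shape, loc=spec.epsilon, scale=spec.omega, size=size, random_state=rng
    )
    return np.mod(lin, TWO_PI)


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator | int | None) -> AngleSample:
    """Draw an :class:`AngleSample` of ``n`` independent angles from ``spec``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return AngleSample(draw(spec, n, rng))


def _wsn_k_range(omega: float) -> int:
    # wrap truncation: generous at large dispersion, never below |k| <= 8
    return int(math.ceil(8 * max(1.0, omega / TWO_PI)))


def density(spec: DistributionSpec, theta: float | np.ndarray) -> np.ndarray:
    """Probability density of ``spec`` at angle(s) ``theta`` (any reals)."""
    th = np.mod(np.asarray(theta, dtype=float), TWO_PI)
    if isinstance(spec, MixtureSpec):
        out = np.zeros_like(th, dtype=float)
        for w, m, k in spec.components:
            out += w * _von_mises_pdf(th, m, k)
        return out
    if spec.family == "uniform":
        return np.full_like(th, 1.0 / TWO_PI, dtype=float)
    if spec.family == "von_mises":
        return _von_mises_pdf(th, spec.mu, spec.kappa)
    if spec.family == "wrapped_cauchy":
        rho = spec.rho
        return (1.0 - rho**2) / (TWO_PI * (1.0 + rho**2 - 2.0 * rho * np.cos(th - spec.mu)))
    # wrapped skew-normal: sum the linear density over wraps
    kmax = _wsn_k_range(spec.omega)
    ks = np.arange(-kmax, kmax + 1)
    pts = th[..., None] + TWO_PI * ks
    return stats.skewnorm.pdf(pts, spec.alpha_shape, loc=spec.epsilon, scale=spec.omega).sum(axis=-1)


def _von_mises_pdf(th: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    # exponentially scaled Bessel keeps this stable at large kappa
    return np.exp(kappa * (np.cos(th - mu) - 1.0)) / (TWO_PI * special.i0e(kappa))


def cdf_grid(spec: DistributionSpec, n_grid: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Numerical CDF of ``spec`` on [0, 2π] by trapezoidal quadrature.

    Returns ``(grid, cdf)`` with cdf[0] = 0 and cdf[-1] ≈ 1.  Used as the
    independent oracle when validating samplers.
    """
    from scipy.integrate import cumulative_trapezoid

    grid = np.linspace(0.0, TWO_PI, n_grid + 1)
    pdf = density(spec, grid)
    cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
    return grid, cdf


# ---------------------------------------------------------------------------
# config-mapping serialization (CLI boundary; angles in the mapping may be
# given in degrees with unit="degrees")

def spec_to_config(spec: DistributionSpec, unit: str = "radians") -> dict:
    conv = (lambda x: float(np.rad2deg(x))) if unit == "degrees" else float
    if isinstance(spec, MixtureSpec):
        return {
            "family": "von_mises_mixture",
            "unit": unit,
            "components": [
                {"weight": w, "mu": conv(m), "kappa": k} for w, m, k in spec.components
            ],
        }
    cfg: dict = {"family": spec.family, "unit": unit}
    for name in ("mu", "kappa", "rho", "epsilon", "omega", "alpha_shape"):
        val = getattr(spec, name)
        if val is not None:
            cfg[name] = conv(val) if name in ("mu", "epsilon") else float(val)
    return cfg


def spec_from_config(cfg: dict) -> DistributionSpec:
    cfg = dict(cfg)
    unit = cfg.pop("unit", "radians")
    if unit not in ("radians", "degrees"):
        raise ValueError(f"unknown unit: {unit!r}")
    ang = (lambda x: float(np.deg2rad(x))) if unit == "degrees" else float
    family = cfg.pop("family")
    if family == "von_mises_mixture":
        comps = [(c["weight"], ang(c["mu"]), c["kappa"]) for c in cfg.pop("components")]
        if cfg:
            raise ValueError(f"unexpected keys in mixture config: {sorted(cfg)}")
        return MixtureSpec(tuple(comps))
    for key in ("mu", "epsilon"):
        if key in cfg:
            cfg[key] = ang(cfg[key])
    return UnimodalSpec(family, **cfg)
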