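"""Circular data containers, descriptive statistics and the f-fold transform.

Angles live on the circle: 0 and 2π are the same point, so ordinary linear
summaries (arithmetic mean, SD) are meaningless.  Everything here stores
angles in radians reduced to the half-open interval [0, 2π); degrees are a
presentation unit accepted at the boundary and echoed back on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

TWO_PI = 2.0 * math.pi

#: below this mean resultant length the mean direction is treated as undefined
R_UNDEFINED_TOL = 1e-12


def _reduce(values: np.ndarray) -> np.ndarray:
    out = np.mod(np.asarray(values, dtype=float), TWO_PI)
    # mod can return 2π for tiny negative inputs; fold it back
    out[out >= TWO_PI] = 0.0
    return out


@dataclass(frozen=True)
class AngleSample:
    """An ordered sample of angles on the circle.

    Parameters
    ----------
    values
        Angles in radians; reduced to [0, 2π) on construction.
    unit_hint
        ``"radians"`` or ``"degrees"`` — records the unit of the source data
        so results can be reported back in it.  Storage is always radians.
    """

    values: np.ndarray
    unit_hint: str = "radians"

    def __post_init__(self) -> None:
        vals = _reduce(np.atleast_1d(np.asarray(self.values, dtype=float)))
        if vals.ndim != 1:
            raise ValueError("AngleSample values must be one-dimensional")
        if vals.size < 1:
            raise ValueError("AngleSample needs at least one angle")
        if self.unit_hint not in ("radians", "degrees"):
            raise ValueError(f"unknown unit_hint: {self.unit_hint!r}")
        object.__setattr__(self, "values", vals)
        self.values.setflags(write=False)

    @classmethod
    def from_degrees(cls, values: Iterable[float]) -> "AngleSample":
        return cls(np.deg2rad(np.asarray(list(values), dtype=float)), unit_hint="degrees")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n(self) -> int:
        return len(self)

    @property
    def degrees(self) -> np.ndarray:
        return np.rad2deg(self.values)


@dataclass(frozen=True)
class DirectionalSummary:
    """First-moment summary of a circular sample.

    ``mean_resultant_length`` (r) is the modulus of the average unit vector:
    0 for perfectly balanced samples, 1 when every angle coincides.  When
    r is numerically zero the mean direction is undefined and flagged.
    """

    n: int
    mean_direction: float  # radians in [0, 2π); nan when undefined
    mean_resultant_length: float
    mean_defined: bool = True


def summarize(sample: AngleSample) -> DirectionalSummary:
    """Circular mean direction and mean resultant length of a sample."""
    theta = sample.values
    c = float(np.sum(np.cos(theta)))
    s = float(np.sum(np.sin(theta)))
    n = theta.size
    r = math.hypot(c, s) / n
    r = min(r, 1.0)
    if r < R_UNDEFINED_TOL:
        return DirectionalSummary(n, math.nan, r, mean_defined=False)
    mean = math.atan2(s, c) % TWO_PI
    return DirectionalSummary(n, mean, r)


def ffold_transform(sample: AngleSample, f: int) -> AngleSample:
    """Map θ → (f·θ) mod 2π.

    Converts a distribution with f-fold rotational symmetry (f equal, evenly
    spaced modes) into a unimodal one, after which a unimodal test such as
    Rayleigh's regains its power.  f must be chosen before looking at the
    data or the type-I error of the downstream test is inflated.
    """
    if not (isinstance(f, (int, np.integer)) and f >= 1):
        raise ValueError(f"f must be a positive integer, got {f!r}")
    return AngleSample(_reduce(f * sample.values), unit_hint=sample.unit_hint)


def circular_distance(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Signed shortest angular displacement from b to a, in (−π, π]."""
    d = np.mod(np.asarray(a) - np.asarray(b) + math.pi, TWO_PI) - math.pi
    return np.where(d == -math.pi, math.pi, d)


def mean_direction_ci(
    sample: AngleSample,
    level: float = 0.95,
    reps: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence arc for the population mean direction.

    Resamples the angles with replacement ``reps`` times, computes each
    resample's mean direction, centres the bootstrap means on the sample mean
    (so the arc never straddles the antipode spuriously) and takes symmetric
    percentiles of the centred deviations.

    Returns ``(lower, upper)`` in the sample's ``unit_hint`` unit.  The arc
    runs counter-clockwise from lower to upper and may cross 0.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if reps < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    summ = summarize(sample)
    if not summ.mean_defined:
        raise ValueError("mean direction undefined (mean resultant length ~ 0)")
    theta = sample.values
    n = theta.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(reps, n))
    boot = theta[idx]
    means = np.arctan2(np.sin(boot).sum(axis=1), np.cos(boot).sum(axis=1))
    dev = circular_distance(means, summ.mean_direction)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(dev, [tail, 1.0 - tail])
    lower = (summ.mean_direction + lo) % TWO_PI
    upper = (summ.mean_direction + hi) % TWO_PI
    if sample.unit_hint == "degrees":
        return float(np.rad2deg(lower)), float(np.rad2deg(upper))
    return float(lower), float(upper)


def read_angles(path: str | Path, unit: str = "degrees") -> AngleSample:
    """Read one angle per line (or single-column CSV) from a text file.

    Blank lines and lines starting with ``#`` are skipped.  A non-numeric
    line raises ``ValueError`` naming the offending line number.
    """
    if unit not in ("degrees", "radians"):
        raise ValueError(f"unknown unit: {unit!r}")
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in line.split(",") if f.strip()]
            if len(fields) != 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected a single angle, got {line!r}"
                )
            try:
                values.append(float(fields[0]))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: not a number: {fields[0].strip()!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: no angles found")
    arr = np.asarray(values, dtype=float)
    if unit == "degrees":
        return AngleSample(np.deg2rad(arr), unit_hint="degrees")
    return AngleSample(arr, unit_hint="radians")


def write_angles(path: str | Path, sample: AngleSample, unit: str | None = None) -> None:
    """Write a sample to a plain-text angle file, one angle per line.

    Degrees are printed with 12 significant digits so a write/read round
    trip reproduces the stored radians to ~1e-12.
    """
    unit = unit or sample.unit_hint
    if unit not in ("degrees", "radians"):
        raise ValueError(f"unknown unit: {unit!r}")
    vals = sample.degrees if unit == "degrees" else sample.values
    with open(path, "w") as fh:
        fh.write(f"# angles in {unit}\n")
        for v in vals:
            fh.write(f"{v:.12g}\n")
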