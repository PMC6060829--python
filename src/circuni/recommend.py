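"""Test-selection guidance distilled from the simulation study.

The mapping is total over four expected-shape categories.  The common
thread: use the most specific test your *a-priori* knowledge licenses —
V-test when the direction is known in advance, Rayleigh for a generic
unimodal departure, Rayleigh after an f-fold transform when modes are
known to be mirrored, Hermans–Rasson when the symmetry is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

SHAPES = (
    "unimodal_with_direction",
    "unimodal_no_direction",
    "multimodal_mirrored",
    "multimodal_unknown_symmetry",
)


@dataclass(frozen=True)
class Recommendation:
    expected_shape: str
    recommended_test: str
    caveats: str
    f: Optional[int] = None


def recommend(expected_shape: str, f: int | None = None) -> Recommendation:
    """Recommend a uniformity test for an expected departure shape.

    ``f`` (the number of mirrored modes) is required for
    ``multimodal_mirrored`` and ignored otherwise.
    """
    if expected_shape == "unimodal_with_direction":
        return Recommendation(
            expected_shape,
            "V-test",
            "The pre-specified direction must be fixed before any inspection "
            "of the data. A significant V-test must always be interpreted "
            "together with a confidence interval for the population mean "
            "direction: if the interval excludes the pre-specified direction, "
            "the data do not support the directional hypothesis.",
        )
    if expected_shape == "unimodal_no_direction":
        return Recommendation(
            expected_shape,
            "Rayleigh test",
            "Most powerful against unimodal (von Mises-like) departures; "
            "nearly blind to symmetric multimodal ones.",
        )
    if expected_shape == "multimodal_mirrored":
        if f is None or f < 2:
            raise ValueError("multimodal_mirrored requires the number of modes f >= 2")
        return Recommendation(
            expected_shape,
            "Rayleigh test (after f-fold transformation)",
            "f has to be decided on or before data inspection; the modes must "
            "be equal, evenly spaced and locally symmetric, otherwise prefer "
            "the Hermans-Rasson test.",
            f=f,
        )
    if expected_shape == "multimodal_unknown_symmetry":
        return Recommendation(
            expected_shape,
            "Hermans-Rasson test",
            "Best all-round power when the number, placement or symmetry of "
            "modes is uncertain; p-values are Monte-Carlo.",
        )
    raise ValueError(f"unknown expected shape {expected_shape!r}; known: {', '.join(SHAPES)}")
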