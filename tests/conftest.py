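import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def circular_arc_contains(lower: float, upper: float, point: float) -> bool:
    """True if the CCW arc from lower to upper contains point (radians)."""
    two_pi = 2.0 * np.pi
    width = (upper - lower) % two_pi
    return (point - lower) % two_pi <= width + 1e-12
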