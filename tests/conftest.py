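import numpy as np
import pytest

from ecogames import GameDecomposition


@pytest.fixture
def standard_dec() -> GameDecomposition:
    """Coexistence game with interior equilibrium at x = 1/2."""
    return GameDecomposition(s_m=0.1, alpha_wm=0.5, alpha_mw=0.3)


@pytest.fixture
def neutral_dec() -> GameDecomposition:
    return GameDecomposition(s_m=0.0, alpha_wm=0.0, alpha_mw=0.0)


def random_valid_decomposition(rng: np.random.Generator) -> GameDecomposition:
    """Sample a decomposition with all payoff entries strictly positive."""
    while True:
        s = rng.uniform(-0.5, 0.5)
        awm = rng.uniform(-0.9, 1.0)
        amw = rng.uniform(-0.9, 1.0)
        if 1 + awm > 0.05 and 1 + s > 0.05 and 1 + s + amw > 0.05:
            return GameDecomposition(s_m=s, alpha_wm=awm, alpha_mw=amw)
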