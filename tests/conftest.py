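import numpy as np
import pytest

from txinit import InitiationModel


def random_model(rng: np.random.Generator, max_steps: int = 3,
                 lo: float = 1e-4, hi: float = 1.0) -> InitiationModel:
    """Random kinetic scheme with rates log-uniform in [lo, hi] 1/s."""
    m = int(rng.integers(1, max_steps + 1))
    rates = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m + 2))
    if rng.random() < 0.5:
        return InitiationModel(tuple(rates[:m]), k_on=rates[m], k_off=rates[m + 1])
    return InitiationModel(tuple(rates[:m]))


@pytest.fixture
def rng():
    return np.random.default_rng(20160)
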