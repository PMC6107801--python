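import numpy as np
import pytest

from afterglow import ModelParams, fixture, predict_afterimage


@pytest.fixture(scope="session")
def predicted():
    """Cached fixture predictions, shared across tests (solves are costly)."""
    cache = {}

    def get(name: str, size: int = 128):
        key = (name, size)
        if key not in cache:
            pair = fixture(name, size=size)
            cache[key] = (pair, predict_afterimage(pair.inducer, pair.contour))
        return cache[key]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(20180817)


@pytest.fixture()
def params():
    return ModelParams()
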