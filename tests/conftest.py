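import pytest

from jawsim import build_model
from jawsim.pipeline import run_mode


@pytest.fixture(scope="session")
def default_model():
    """The default synthetic 150-strand model, built once per session."""
    return build_model()


@pytest.fixture(scope="session")
def sim(default_model):
    """Factory returning (and caching) full-cycle simulation results."""
    cache = {}

    def get(mode):
        if mode not in cache:
            cache[mode] = run_mode(mode, model=default_model)
        return cache[mode]

    return get
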