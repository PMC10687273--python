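import numpy as np
import pytest

import scsol as s


@pytest.fixture(scope="session")
def codeine():
    return s.builtin_codeine_dataset()


@pytest.fixture(scope="session")
def fast_config():
    """Small but deterministic multi-start budget for unit tests."""
    return s.FitConfig(n_starts=6, seed=7)


@pytest.fixture(scope="session")
def fits32(codeine):
    """Reference refits of all nine models at the full multi-start budget.

    Shared across the suite so the expensive fits run once.
    """
    config = s.FitConfig(n_starts=32, seed=0)
    return {
        name: s.make_model(name, codeine).fit(config) for name in s.MODEL_NAMES
    }
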