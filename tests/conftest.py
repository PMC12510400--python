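import warnings

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # super-model knot values are weakly identified by design; their
    # R-hat warnings are expected and would flood the test output
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*R-hat.*")
        yield
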