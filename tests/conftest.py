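import warnings

import numpy as np
import pytest

from respchaos import cpg, fixtures

# The CPG regime certificates and the burst-level statistics are shared by
# several test modules; simulate each preset once per session.


@pytest.fixture(scope="session")
def preset_traces():
    traces = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in cpg.PRESET_NAMES:
            traces[name] = cpg.simulate(cpg.load_preset(name, seed=1))
    return traces


@pytest.fixture(scope="session")
def logistic_series():
    return fixtures.gen_logistic(5000, x0=0.123)


@pytest.fixture(scope="session")
def henon_series():
    return fixtures.gen_henon(10_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
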