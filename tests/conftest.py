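import numpy as np
import pytest

import spikeamp as sa


@pytest.fixture(scope="session")
def bench20() -> sa.PatternSet:
    """The 40+40 benchmark at N=20 used across integration tests."""
    return sa.make_benchmark(20, seed=0)


@pytest.fixture(scope="session")
def trained20(bench20) -> sa.NetworkModel:
    """A model fitted on the benchmark with auto-calibrated input gain."""
    return sa.fit(bench20)


@pytest.fixture(scope="session")
def eval20(trained20, bench20) -> sa.Evaluation:
    return sa.evaluate(trained20, bench20)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
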