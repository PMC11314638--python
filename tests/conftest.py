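import numpy as np
import pytest

import riskreplay as rr


@pytest.fixture(scope="session")
def schema():
    return rr.default_schema()


@pytest.fixture(scope="session")
def small_stream():
    """A 3-batch drifting stream shared by read-only tests."""
    cfg = rr.SimulationConfig(n_batches=3, patients_per_batch=40, seed=7)
    return rr.generate_stream(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def fitted_stats(small_stream, schema):
    return rr.fit_normalizer(small_stream.batches[0], schema)
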