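import logging

import numpy as np
import pytest

from pwasoft.data_model import BatchTimeSeries


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("pwasoft").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_batch(rng):
    """A fully observed 6-input, 2-output batch with random values."""
    n = 40
    return BatchTimeSeries(
        batch_id="rand",
        u=rng.normal(size=(n, 6)),
        y=rng.normal(size=(n, 2)),
        y_observed_mask=np.ones(n, dtype=bool),
    )
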