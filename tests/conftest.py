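import numpy as np
import pytest

from slicerank import BatchRanking, SessionConfig, initialize_session


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_session():
    """Eight items, fresh state, deterministic seed."""
    return initialize_session([f"i{k}" for k in range(8)], SessionConfig(rng_seed=1))


def make_session(n_items, seed=0, **config_kwargs):
    config = SessionConfig(rng_seed=seed, **config_kwargs)
    return initialize_session([f"i{k:04d}" for k in range(n_items)], config)


def batch_of(ids, annotator="a", timestamp=0):
    return BatchRanking(ordered_items=tuple(ids), annotator_id=annotator,
                        timestamp=timestamp)
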