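import numpy as np
import pytest

from phasematch.sim_experiments import run_condition_suite

_TRACE_CACHE = {}


@pytest.fixture(scope="session")
def condition_traces():
    """Lazily simulated condition traces, shared across the whole session."""

    def get(*ids):
        missing = [c for c in ids if c not in _TRACE_CACHE]
        if missing:
            _TRACE_CACHE.update(run_condition_suite(missing))
        return {c: _TRACE_CACHE[c] for c in ids}

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
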