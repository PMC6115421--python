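import numpy as np
import pytest

import netblocks
import netblocks.consensus
import netblocks.wsbm
from netblocks.types import Partition, WSBMParams
from netblocks.wsbm import sample_network

_orig_fit = netblocks.wsbm.fit_wsbm


def _checked_fit(*args, **kwargs):
    post = _orig_fit(*args, **kwargs)
    trace = post.elbo_trace
    if trace.size > 1:
        diffs = np.diff(trace)
        floor = -1e-6 * max(1.0, np.abs(trace).max())
        assert (diffs >= floor).all(), (
            f"variational lower bound decreased: min step {diffs.min()}"
        )
    return post


@pytest.fixture(autouse=True)
def monotone_elbo_everywhere(monkeypatch):
    """Every VB run in the suite asserts lower-bound monotonicity."""
    for mod in (netblocks.wsbm, netblocks.consensus, netblocks):
        monkeypatch.setattr(mod, "fit_wsbm", _checked_fit)
    yield


@pytest.fixture
def two_cliques():
    """Two 5-node unit-weight cliques, no between edges."""
    A = np.zeros((10, 10))
    A[:5, :5] = 1.0
    A[5:, 5:] = 1.0
    np.fill_diagonal(A, 0.0)
    labels = np.array([1] * 5 + [2] * 5)
    return A, Partition(labels, 2)


def planted_network(n=60, k=3, seed=2, within_rate=0.9, between_rate=0.2,
                    within_mean=3.0, between_mean=1.0, sd=0.5):
    """Strongly separated planted-block network plus its truth."""
    labels = 1 + np.arange(n) % k
    er = np.full((k, k), between_rate)
    np.fill_diagonal(er, within_rate)
    wm = np.full((k, k), between_mean)
    np.fill_diagonal(wm, within_mean)
    params = WSBMParams(er, wm, np.full((k, k), sd**2))
    part = Partition(labels, k)
    W = sample_network(params, part, seed=seed)
    return W, part, params


@pytest.fixture
def planted3():
    return planted_network()
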