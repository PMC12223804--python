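import numpy as np
import pytest

from mablwe import Ensemble, ROOT_PARENT, Walker


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ensemble(weights, coords=None, tau=1.0, iteration=0):
    """Build an ensemble from a weight vector (coords default to zeros)."""
    weights = np.asarray(weights, dtype=float)
    if coords is None:
        coords = np.zeros((len(weights), 1))
    walkers = [Walker(id=i, parent_id=ROOT_PARENT, weight=float(w),
                      coords=np.atleast_1d(coords[i]))
               for i, w in enumerate(weights)]
    return Ensemble(iteration=iteration, walkers=walkers, tau=tau)


@pytest.fixture
def uniform_ensemble():
    def _make(n, tau=1.0):
        return make_ensemble(np.full(n, 1.0 / n), tau=tau)
    return _make
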