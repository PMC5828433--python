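import numpy as np
import pytest

from neuralcox import SurvivalDataset


@pytest.fixture
def toy6():
    """Six records with mixed censoring, used by several hand oracles."""
    return SurvivalDataset(
        covariates=np.array([[0.5, -1.0], [1.0, 0.2], [-0.3, 0.8],
                             [0.0, 0.0], [-1.2, 0.5], [0.7, -0.4]]),
        time=np.array([2.0, 5.0, 1.0, 8.0, 3.0, 3.0]),
        event=np.array([1, 0, 1, 1, 0, 1]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_survival(rng, n, d=3, censor_frac=0.3, tie_times=False):
    """Random dataset with events, optional tied observed times."""
    X = rng.normal(size=(n, d))
    t = rng.exponential(2.0, size=n)
    if tie_times:
        t = np.round(t, 1)
    e = (rng.random(n) > censor_frac).astype(int)
    if e.sum() == 0:
        e[0] = 1
    return SurvivalDataset(covariates=X, time=t, event=e)
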