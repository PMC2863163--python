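import numpy as np
import pytest

from sepindex import decompose_risk_sets


@pytest.fixture
def toy():
    """Four subjects, times (2,1,1,3), events (1,1,0,0): N=3, k=2, one
    failure/censoring tie at t=1."""
    time = np.array([2.0, 1.0, 1.0, 3.0])
    event = np.array([1, 1, 0, 0])
    return time, event, decompose_risk_sets(time, event)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_survival(rng, n=60, censor=0.3, ties=False):
    """A random censored dataset, optionally with tied times."""
    t = rng.exponential(1.0, n)
    if ties:
        t = np.ceil(t * 4) / 4  # quarter-unit grid forces ties
    c = rng.exponential(1.0 / censor, n) if censor > 0 else np.full(n, np.inf)
    x = np.minimum(t, c)
    e = (t <= c).astype(int)
    if e.sum() == 0:
        e[np.argmin(x)] = 1
    return x, e


@pytest.fixture
def random_datasets(rng):
    """A batch of small random datasets (with and without ties) plus
    covariates, for identity checks."""
    out = []
    for i in range(25):
        x, e = random_survival(rng, n=40, censor=0.4, ties=(i % 2 == 0))
        z = rng.normal(0, 1, 40) if i % 3 else (rng.random(40) < 0.5).astype(float)
        out.append((x, e, z))
    return out
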