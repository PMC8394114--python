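import numpy as np
import pytest

from tebench import EmbeddingSpec, SimConfig, estimate_te, simulate
from tebench.simulators import trial_seed


@pytest.fixture(scope="session")
def independent_pairs():
    """50 independent unit-variance Gaussian white-noise pairs, N=200."""
    pairs = []
    for t in range(50):
        rng = np.random.default_rng(trial_seed(1000, t))
        pairs.append((rng.standard_normal(200), rng.standard_normal(200)))
    return pairs


@pytest.fixture(scope="session")
def independent_medians(independent_pairs):
    """Median TE of every estimator over the independent pairs at tau=1."""
    settings = {"LIN": {}, "KNN": {"k": 5}, "FBR": {"Q": 4},
                "KDE": {"alpha": 1.5}, "DVP": {}}
    meds = {}
    for est, params in settings.items():
        te = [estimate_te(x, y, EmbeddingSpec(), est, params).value
              for x, y in independent_pairs]
        meds[est] = float(np.median(te))
    return meds


@pytest.fixture(scope="session")
def linear_trial():
    """One reference trial of the coupled linear AR model (a=0.5, N=200)."""
    return simulate(SimConfig(model="linear", a=0.5, seed=7))
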