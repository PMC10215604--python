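import numpy as np
import pytest

from galslo.ga import Evaluator, GaConfig
from galslo.synthetic import FeatureFixtureConfig, generate_feature_fixture


@pytest.fixture(scope="session")
def small_cache():
    """Reduced search space: 3 lengths x 4 leads, informative leads 2 and 4,
    64-wide Gaussian features with planted separation."""
    cfg = FeatureFixtureConfig(lengths=(1, 2, 3), leads=(1, 2, 3, 4),
                               informative_leads=(2, 4), feature_width=64,
                               n_train_patients=6, n_test_patients=3,
                               segments_per_patient=4, seed=1)
    return generate_feature_fixture(cfg)


@pytest.fixture(scope="session")
def small_ga_cfg():
    return GaConfig(lengths=(1, 2, 3), leads=(1, 2, 3, 4), seed=0)


FAST_HEAD = {"epochs": 15, "hidden": (32,)}


@pytest.fixture()
def small_evaluator(small_cache):
    return Evaluator(small_cache, head="mlp", seed=1, head_kwargs=dict(FAST_HEAD))


def numerical_gradient(f, arr, eps=1e-6):
    """Central-difference gradient of scalar f() with respect to arr in place."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        lp = f()
        arr[i] = old - eps
        lm = f()
        arr[i] = old
        g[i] = (lp - lm) / (2 * eps)
    return g
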