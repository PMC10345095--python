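import numpy as np
import pytest

from mmmi.cohort import CohortSpec, generate_cohort
from mmmi.network import ModelConfig


def small_spec(**kw):
    """A scaled-down cohort spec for unit tests: tiny bags, low dimension."""
    base = dict(n_patients=60, feature_dim=8,
                bag_size_range={5: (3, 8), 10: (4, 12), 20: (6, 20)},
                seed=7)
    base.update(kw)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec())


@pytest.fixture(scope="session")
def small_config():
    return ModelConfig(feature_dim=8, n_variables=17, embed_dim=8,
                       fusion_dim=8, attn_hidden=8, classifier_hidden=(8,))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
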