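import numpy as np
import pytest
from hypothesis import settings

from pcthmc import compute_class_weights, parse_funcat_labels

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_hierarchy():
    """Five-class toy tree: 1, 2, 2/1, 2/2, 3 (vector in that order)."""
    return parse_funcat_labels(["1", "2/1", "2/2", "3"])


@pytest.fixture(scope="session")
def toy_weights(toy_hierarchy):
    return compute_class_weights(toy_hierarchy, 0.75)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
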