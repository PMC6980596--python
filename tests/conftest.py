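import numpy as np
import pytest

import craniomorph as cm


@pytest.fixture(scope="session")
def sym31():
    return cm.cranial31_symmetry()


@pytest.fixture(scope="session")
def part31():
    return cm.cranial31_partition()


@pytest.fixture(scope="session")
def toy_schema():
    return cm.make_template("toy")


@pytest.fixture(scope="session")
def small_dataset():
    """Three small cranial categories with the full generative structure."""
    spec = cm.SyntheticSpec(
        n_per_group={"antero-posterior": 15, "non-deformed": 20, "oblique": 15},
        seed=1234,
    )
    return cm.simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_fit(small_dataset, sym31):
    return cm.gpa_object_symmetry(small_dataset, sym31)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
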