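import numpy as np
import pytest

from ecgmtl.synthetic import SyntheticSpec, make_dataset
from ecgmtl.taxonomy import cpsc_hierarchy, ptbxl_hierarchy


@pytest.fixture(scope="session")
def cpsc():
    return cpsc_hierarchy()


@pytest.fixture(scope="session")
def ptbxl():
    return ptbxl_hierarchy()


@pytest.fixture(scope="session")
def tiny_spec():
    """Small balanced dataset: 6 records per fine class, 4 s at 100 Hz."""
    h = cpsc_hierarchy()
    return SyntheticSpec(hierarchy=h, frequencies={c: 6 for c in h.fine_classes},
                         rate=100.0, duration=4.0, noise_sd=0.05,
                         multilabel_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return make_dataset(tiny_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
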