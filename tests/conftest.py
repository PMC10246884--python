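import numpy as np
import pytest

from citrusgen.synthetic import generate_dataset, DatasetConfig
from citrusgen.data import load_manifest


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small deterministic orchard dataset shared across tests.

    6 samples x 8 days at 32x32, no frame drop-out so counting tests are
    exact.
    """
    root = tmp_path_factory.mktemp("orchard")
    manifest = generate_dataset(
        6, 8, 1, root, seed=123,
        config=DatasetConfig(image_size=(32, 32), dropout=0.0))
    return manifest


@pytest.fixture(scope="session")
def tiny_records(tiny_dataset):
    return load_manifest(tiny_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
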