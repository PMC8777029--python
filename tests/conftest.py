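import numpy as np
import pytest

from segan3d.phantom import PhantomParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory):
    """A small phantom dataset shared by training tests: 2 labeled,
    1 unlabeled, 1 validation, 1 test volume of 32x32x16 voxels."""
    out = tmp_path_factory.mktemp("tiny_dataset")
    return generate_dataset(2, 1, 1, 1, PhantomParams(shape=(32, 32, 16), seed=42),
                            out)
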