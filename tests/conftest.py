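import numpy as np
import pytest

from cseanet import PhantomSpec, generate_dataset
from cseanet.preprocess import split_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def tiny_phantom_dir(tmp_path_factory):
    """A small 48x48 phantom dataset with split labels, shared across tests."""
    out = tmp_path_factory.mktemp("phantom")
    spec = PhantomSpec(size=(48, 48), nodule_radius=(3.0, 7.0))
    records = generate_dataset(12, spec, out, seed=11)
    records = split_dataset(records, seed=11)
    from cseanet.phantom import write_manifest

    write_manifest(out / "manifest.csv", records)
    return out


@pytest.fixture(scope="session")
def tiny_records(tiny_phantom_dir):
    from cseanet.phantom import read_manifest

    return read_manifest(tiny_phantom_dir / "manifest.csv")
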