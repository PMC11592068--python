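import numpy as np
import pytest
from hypothesis import settings

from ucapsnet import Label, PhantomConfig, make_dataset, make_phantom

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom_config_64():
    return PhantomConfig(size=64, seed=1234)


@pytest.fixture(scope="session")
def small_dataset_64(phantom_config_64):
    """30 phantoms (10 per class) at 64 px, deterministic."""
    return make_dataset(10, phantom_config_64)


@pytest.fixture()
def busi_dir(tmp_path):
    """A tiny BUSI-layout directory written from generated phantoms."""
    from ucapsnet import save_dataset

    recs = make_dataset(2, PhantomConfig(size=64, seed=7))
    save_dataset(recs, tmp_path)
    return tmp_path
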