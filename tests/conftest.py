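import numpy as np
import pytest

from fuseqa import PhantomSpec, RunConfig, make_dataset
from fuseqa.training import init_state


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_config(**overrides) -> RunConfig:
    """Smallest config the architecture constraints admit (side 48)."""
    base = dict(
        image_side=48,
        channel_widths=(8, 16, 32),
        disc_widths=(8, 16, 32, 64),
        batch_size=4,
        epochs=2,
        seed=0,
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture
def small_config():
    return tiny_config()


@pytest.fixture
def small_state(small_config):
    return init_state(small_config)


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """Four phantom pairs x five graded fusions at side 48 (20 records)."""
    out = tmp_path_factory.mktemp("phantoms")
    manifest = make_dataset(PhantomSpec(side=48, n_pairs=4, seed=7), out)
    return manifest, out
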