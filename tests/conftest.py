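import numpy as np
import pytest

from bbbdetect import synthetic
from bbbdetect.preprocess import Beat


@pytest.fixture(scope="session")
def small_config():
    """A quick, still class-separable generator configuration."""
    return synthetic.GeneratorConfig(
        n_train=(240, 60, 60), n_test=(120, 30, 30),
        n_patients_train=(6, 2, 2), n_patients_test=(3, 1, 1), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthetic.generate_dataset(small_config)


def make_beat(label="NORM", rr=0.8, record_id="r0", r_index=0, seed=0):
    """A single synthetic normalized two-lead beat for unit tests."""
    rng = np.random.default_rng(seed)
    cfg = synthetic.GeneratorConfig()
    return synthetic.sample_beat(label, cfg, rng, record_id=record_id,
                                 r_index=r_index)


@pytest.fixture
def one_beat():
    return make_beat()
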