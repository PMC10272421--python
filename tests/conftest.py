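import numpy as np
import pytest

from mieeg.preprocess import EpochSet
from mieeg.synth import SynthConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """One-subject 4-class dataset at desk scale (8 ch, 64 Hz, 4 s)."""
    cfg = SynthConfig(n_subjects=1, trials_per_class=10, C=8, fs=64.0,
                      T_seconds=4.0, snr=2.0, subject_shift_sd=0.0, seed=7)
    return make_dataset(cfg)[0]


@pytest.fixture
def tiny_epochs(rng):
    """Unstructured noise epochs for shape/contract tests."""
    data = rng.standard_normal((12, 6, 128))
    labels = np.tile([1, 2, 3, 4], 3)
    return EpochSet(data=data, labels=labels, fs=64.0)
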