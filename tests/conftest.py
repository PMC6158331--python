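import numpy as np
import pytest

from szdet.features import feature_matrix
from szdet.preprocess import run as preprocess_run
from szdet.synth import Recording, SynthConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_config():
    """A small one-seizure block config used across module tests."""
    return SynthConfig(
        block_duration_s=120.0,
        seizure_onset_s=60.0,
        seizure_duration_s=20.0,
        n_channels=4,
        soz_channels=(0,),
        seed=7,
    )


def make_recording(signal, fs=256.0, annotations=None, groups=None):
    """Wrap a raw (channels x samples) array in a Recording."""
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    n_ch = signal.shape[0]
    return Recording(
        signal=signal,
        fs=fs,
        channel_names=[f"ch{i}" for i in range(n_ch)],
        electrode_groups=groups or {"e0": list(range(n_ch))},
        annotations=annotations or [],
    )


@pytest.fixture(scope="session")
def small_lvfa_blocks():
    """Four 300-s LVFA blocks through preprocess + features (shared; ~2 s)."""
    cfg = SynthConfig(
        block_duration_s=300.0,
        seizure_onset_s=150.0,
        seizure_duration_s=40.0,
        n_channels=4,
        soz_channels=(0, 1),
        seed=5,
    )
    return [feature_matrix(preprocess_run(r)) for r in make_dataset(4, cfg, seed=99)]
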