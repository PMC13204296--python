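import numpy as np
import pytest

from tckey.signal_data import LabeledWindowSet
from tckey.synthgen import SynthConfig, generate_dataset


def make_window_set(n=5, C=4, T=40, fs=200.0, n_classes=26, seed=0):
    rng = np.random.default_rng(seed)
    return LabeledWindowSet(
        data=rng.standard_normal((n, C, T)),
        labels=rng.integers(0, n_classes, n),
        subject_ids=np.array([f"S{i % 2}" for i in range(n)]),
        session_ids=np.array(["T1"] * n),
        fs=fs,
        window_s=T / fs,
        n_classes=n_classes,
    )


@pytest.fixture
def small_ws():
    return make_window_set()


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(n_classes=6, n_channels=8, fs=2000.0, window_s=0.2, reps_per_class=10, snr_db=20.0, seed=42)


@pytest.fixture(scope="session")
def synth_ds(synth_cfg):
    return generate_dataset(synth_cfg)
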