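import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for edf_ref helper

from eegmind.containers import EEGRecording
from eegmind.synth import generate_dataset, two_class_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """3-channel, 4 s, 128 Hz recording with two events."""
    fs = 128.0
    data = rng.standard_normal((3, int(4 * fs))) * 20.0
    return EEGRecording(
        data, fs, ["Fz", "Cz", "Pz"], events=[(64, "stimulus"), (300, "rest")]
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small normalized 2-class benchmark dataset (20 windows/class)."""
    from eegmind.preprocessing import normalize_windows

    ds, truth = generate_dataset(two_class_spec(n_per_class=20, seed=7))
    return normalize_windows(ds), truth
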