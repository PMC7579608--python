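import numpy as np
import pytest

from microstate_lab import (
    EpochSet,
    StateDynamics,
    make_canonical_templates,
    make_montage,
    simulate_recording,
)


@pytest.fixture(scope="session")
def montage32():
    return make_montage(32)


@pytest.fixture(scope="session")
def canon32(montage32):
    return make_canonical_templates(montage32)


@pytest.fixture(scope="session")
def noisefree_recording(canon32):
    """One noise-free dataset: 10 x 2 s epochs at 125 Hz."""
    dyn = StateDynamics((74.0, 69.0, 67.0, 64.0), snr=np.inf, gfp_uv=10.0)
    return simulate_recording(canon32, dyn, n_epochs=10, seed=42)


@pytest.fixture()
def epochs_factory(montage32):
    """Build an EpochSet from raw (n_epochs, n_ch, n_samples) data."""

    def build(data, fs=125.0):
        data = np.asarray(data, dtype=float)
        return EpochSet(data, fs, data.shape[2] / fs, montage32)

    return build
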