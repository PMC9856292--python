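import numpy as np
import pytest

from msdoc import EEGRecording, GroundTruth, default_montage, make_templates
from msdoc.synth import synthesize_eeg, uniform_offdiagonal


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def templates(montage):
    return make_templates(montage, 4, seed=1)


@pytest.fixture(scope="session")
def truth(templates):
    return GroundTruth(
        templates=templates,
        transition_probs=uniform_offdiagonal(4),
        mean_dwell_ms=(85.0, 85.0, 73.0, 95.0),
        snr=5.0,
    )


@pytest.fixture(scope="session")
def noisy_recording(truth):
    """60 s synthetic recording at SNR 5 with its realised truth."""
    rec, realized = synthesize_eeg(truth, 60.0, 200.0, seed=7)
    return rec, realized


@pytest.fixture(scope="session")
def clean_recording(truth):
    """Noise-free synthetic recording (every sample is exactly a template)."""
    import dataclasses

    clean = dataclasses.replace(truth, snr=np.inf)
    rec, realized = synthesize_eeg(clean, 30.0, 200.0, seed=3)
    return rec, realized


def make_recording(data, fs=200.0):
    """Recording over a generic montage matching the data width."""
    from msdoc import Montage

    data = np.atleast_2d(np.asarray(data, float))
    return EEGRecording(
        data, fs=fs, montage=Montage(tuple(f"ch{i}" for i in range(data.shape[1])))
    )
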