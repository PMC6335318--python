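import numpy as np
import pytest

import eegfmriqc as q


@pytest.fixture(scope="session")
def montage():
    return q.standard_montage()


@pytest.fixture(scope="session")
def small_montage(montage):
    return montage.subset(["C3", "C4", "Cz"])


@pytest.fixture(scope="session")
def pre_acquisition_session():
    """Pulse artifact, no gradient: 120 s at 500 Hz (detector test scale)."""
    params = q.condition_params("pre_acquisition", seed=3, fs=500,
                                duration=120)
    return q.generate_eeg_session(params)


@pytest.fixture(scope="session")
def simultaneous_session():
    """Gradient + pulse artifacts: 80 s at 1000 Hz."""
    params = q.condition_params("simultaneous", seed=2, fs=1000, duration=80)
    return q.generate_eeg_session(params)


def match_rate(found_s, true_s, tol=0.010):
    """Sensitivity and precision of detected event times vs ground truth."""
    found_s = np.asarray(found_s)
    true_s = np.asarray(true_s)
    sens = np.mean([np.min(np.abs(found_s - t)) <= tol for t in true_s])
    prec = np.mean([np.min(np.abs(true_s - f)) <= tol for f in found_s])
    return sens, prec
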