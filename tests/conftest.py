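import numpy as np
import pytest

from erpmarkers import SimulationConfig
from erpmarkers.sigproc import Recording


@pytest.fixture(scope="session")
def fast_cfg():
    """Small, quick simulation configuration shared across tests."""
    return SimulationConfig(seed=42, n_subjects=10, trials_per_intensity=30,
                            mmn_n_stimuli=400)


@pytest.fixture(scope="session")
def ldaep_rec(fast_cfg):
    from erpmarkers.synthgen import gen_ldaep_recording
    return gen_ldaep_recording(fast_cfg)


@pytest.fixture(scope="session")
def mmn_rec(fast_cfg):
    from erpmarkers.synthgen import gen_mmn_recording
    return gen_mmn_recording(fast_cfg)


def sine_recording(freq, amp=1.0, fs=1000.0, duration=10.0, channels=("Cz",),
                   paradigm="resting"):
    t = np.arange(int(duration * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (len(channels), 1))
    return Recording(subject_id="T001", paradigm=paradigm,
                     channel_labels=list(channels), sampling_rate=fs, data=data)


@pytest.fixture(scope="session")
def clinical_cohort():
    from erpmarkers.synthgen import gen_clinical_cohort
    cfg = SimulationConfig(seed=7, n_subjects=52)
    return gen_clinical_cohort(cfg)
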