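import numpy as np
import pandas as pd
import pytest

import hmdeeg as H
from hmdeeg.preprocess import EpochSet


@pytest.fixture(scope="session")
def berger_pair():
    """Paired Oculus-like VR / clean No-VR eyes-task sessions, 20 trials
    per task at the reduced 19-channel / 500 Hz scale."""
    cfg = H.test_preset(seed=11, n_trials_per_task=20,
                        hmd_profile=H.OCULUS_LIKE)
    return (H.simulate_berger_session(cfg, "VR"),
            H.simulate_berger_session(cfg, "No-VR"), cfg)


@pytest.fixture(scope="session")
def spectral_results(berger_pair):
    from hmdeeg.report import spectral_branch
    vr, novr, _ = berger_pair
    return spectral_branch(vr, novr)


@pytest.fixture(scope="session")
def sep_pair():
    """Paired SEP sessions at the full 500-stimulation count, reduced
    channel/rate scale."""
    cfg = H.test_preset(seed=0, sep=H.SEPConfig())
    return (H.simulate_sep_session(cfg, "VR"),
            H.simulate_sep_session(cfg, "No-VR"), cfg)


def make_epochs(data, fs, channels, tmin=0.0):
    """EpochSet straight from an array (trials x channels x samples)."""
    data = np.asarray(data, dtype=float)
    tmax = tmin + data.shape[2] / fs
    meta = pd.DataFrame({"onset_s": np.arange(data.shape[0], dtype=float),
                         "label": "stim"})
    return EpochSet(data=data, tmin=tmin, tmax=tmax, fs=fs,
                    channels=tuple(channels), metadata=meta)
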