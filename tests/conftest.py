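import numpy as np
import pytest

from betaburst.data import TrialSet


def make_trialset(signals, fs=2000.0, epoch=(-3.0, 0.1), channels=None,
                  subjects=None, emg=None):
    """TrialSet from raw per-trial signals.

    ``signals``: array [trial x channel x time] (or [trial x time] for a
    single channel).  The time axis is built from ``epoch`` and ``fs``.
    """
    sig = np.asarray(signals, dtype=float)
    if sig.ndim == 2:
        sig = sig[:, None, :]
    n_trials, n_ch, n_t = sig.shape
    times = epoch[0] + np.arange(n_t) / fs
    if channels is None:
        channels = (["C4-hjorth"] if n_ch == 1
                    else [f"ch{i}" for i in range(n_ch)])
    if subjects is None:
        subjects = np.array(["S01"] * n_trials, dtype=object)
    if emg is None:
        emg = np.zeros((n_trials, n_t))
    return TrialSet(eeg=sig, emg=np.asarray(emg, dtype=float), times=times,
                    fs=fs, channels=list(channels),
                    subjects=np.asarray(subjects, dtype=object),
                    trial_ids=np.arange(n_trials))


def epoch_times(fs=2000.0, epoch=(-3.0, 0.1)):
    n_t = int(round((epoch[1] - epoch[0]) * fs)) + 1
    return epoch[0] + np.arange(n_t) / fs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
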