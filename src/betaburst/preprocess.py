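"""Re-referencing, Hjorth spatial filtering and pre-stimulus artifact rejection.

The analysis channel is the Hjorth transform of the electrode over the
contralateral motor cortex: the central electrode minus the mean of its four
surrounding electrodes (C4 - mean(FC2, FC6, CP2, CP6)), a local spatial
high-pass that emphasizes activity generated beneath the central site.
Because the Hjorth weights sum to zero, applying it after common-average
re-referencing gives the same result as applying it alone.

Trials are rejected when the analysis channel, within the 1 s window
preceding the stimulus, shows a maximum absolute deflection above 50 uV or a
Pearson kurtosis above 4 (a Gaussian signal has Pearson kurtosis 3, so the
rule flags heavy-tailed transients such as blinks and muscle activity).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import TrialSet

__all__ = [
    "common_average_reference",
    "hjorth_transform",
    "reject_artifacts",
]

DEFAULT_CENTRAL = "C4"
DEFAULT_SURROUND = ("FC2", "FC6", "CP2", "CP6")


def common_average_reference(trials: TrialSet) -> TrialSet:
    """Subtract the instantaneous mean over channels from every channel."""
    if trials.eeg.shape[1] < 2:
        raise ValueError("common average reference requires >= 2 channels")
    car = trials.eeg - trials.eeg.mean(axis=1, keepdims=True)
    return replace(trials, eeg=car)


def hjorth_transform(trials: TrialSet, central: str = DEFAULT_CENTRAL,
                     surround=DEFAULT_SURROUND) -> TrialSet:
    """central - mean(surround), returned as a single-channel trial set."""
    missing = [ch for ch in (central, *surround) if ch not in trials.channels]
    if missing:
        raise KeyError(f"missing channel(s): {missing}")
    surround_idx = [trials.channel_index(ch) for ch in surround]
    out = trials.channel(central) - trials.eeg[:, surround_idx, :].mean(axis=1)
    return replace(trials, eeg=out[:, None, :],
                   channels=[f"{central}-hjorth"])


def reject_artifacts(
    trials: TrialSet,
    window: tuple[float, float] = (-1.0, 0.0),
    amp_thresh_uv: float = 50.0,
    kurt_thresh: float = 4.0,
    channel: str | None = None,
) -> tuple[TrialSet, pd.DataFrame]:
    """Drop trials with pre-stimulus artifacts on the analysis channel.

    The window is closed on the left and open at the stimulus.  Kurtosis is
    the Pearson convention (normal ~ 3).  Returns the retained trials and a
    report with one row per input trial (columns: trial, subject, max_abs_uv,
    kurtosis, rejected, reason).
    """
    if window[0] < trials.times[0] or window[1] > trials.times[-1]:
        raise ValueError("rejection window outside the epoch")
    if channel is None:
        if len(trials.channels) != 1:
            raise ValueError(
                "multi-channel trial set: name the channel to evaluate")
        channel = trials.channels[0]
    x = trials.channel(channel)
    m = trials.time_mask(window[0], window[1], closed="left")
    seg = x[:, m]

    max_abs = np.abs(seg).max(axis=1)
    kurt = stats.kurtosis(seg, axis=1, fisher=False, bias=True)
    amp_bad = max_abs > amp_thresh_uv
    kurt_bad = kurt > kurt_thresh
    rejected = amp_bad | kurt_bad
    reason = np.where(
        amp_bad & kurt_bad, "amplitude+kurtosis",
        np.where(amp_bad, "amplitude", np.where(kurt_bad, "kurtosis", "")))

    report = pd.DataFrame({
        "trial": trials.trial_ids,
        "subject": trials.subjects,
        "max_abs_uv": max_abs,
        "kurtosis": kurt,
        "rejected": rejected,
        "reason": reason,
    })
    if rejected.all():
        raise ValueError("no trials survive artifact rejection")
    return trials.select(~rejected), report
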