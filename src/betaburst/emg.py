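"""MEP amplitude extraction and EMG-based trial exclusion.

The motor-evoked potential (MEP) amplitude is the peak-to-peak voltage
difference of the EMG inside +20 to +40 ms after the stimulus.  Two filters
remove trials contaminated by voluntary muscle activity before the natural
log transform:

* pre-stimulus activity: per-sample EMG power (squared demeaned voltage) in
  -25 to -5 ms is compared against a per-subject limit of Q75 + 3*IQR of the
  pooled pre-stimulus power samples; trials in which more than half of the
  window samples exceed the limit are excluded;
* template correlation: trials whose MEP-window waveform correlates at
  r <= 0.40 with the subject's mean MEP waveform (computed once, over the
  trials surviving the first filter) are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import TrialSet

__all__ = [
    "mep_amplitude",
    "prestim_emg_filter",
    "template_correlation_filter",
    "log_transform",
    "process_emg",
]

MEP_WINDOW = (0.020, 0.040)
PRESTIM_WINDOW = (-0.025, -0.005)


def mep_amplitude(trials: TrialSet,
                  window: tuple[float, float] = MEP_WINDOW) -> np.ndarray:
    """Peak-to-peak EMG voltage (mV) inside the MEP window, per trial."""
    if window[0] < trials.times[0] or window[1] > trials.times[-1]:
        raise ValueError("MEP window outside the epoch")
    seg = trials.emg[:, trials.time_mask(*window)]
    return seg.max(axis=1) - seg.min(axis=1)


def _records_skeleton(trials: TrialSet) -> pd.DataFrame:
    return pd.DataFrame({
        "subject": trials.subjects,
        "trial": trials.trial_ids,
        "peak_to_peak_mv": mep_amplitude(trials),
        "log_amplitude": np.nan,
        "prestim_power": np.nan,
        "template_r": np.nan,
        "excluded": False,
        "reason": "",
    })


def _flag(records: pd.DataFrame, mask, reason: str) -> None:
    newly = np.asarray(mask) & ~records["excluded"].to_numpy()
    records.loc[newly, "excluded"] = True
    records.loc[newly, "reason"] = reason


def prestim_emg_filter(records: pd.DataFrame, trials: TrialSet,
                       window: tuple[float, float] = PRESTIM_WINDOW
                       ) -> pd.DataFrame:
    """Flag trials with sustained pre-stimulus EMG activity.

    Per subject, the limit is Q75 + 3*IQR of all trials' per-sample power
    (squared demeaned voltage) in the window; a trial is flagged when more
    than half of its window samples exceed that limit.
    """
    if window[0] < trials.times[0] or window[1] > trials.times[-1]:
        raise ValueError("pre-stimulus window outside the epoch")
    seg = trials.emg[:, trials.time_mask(*window)]
    power = (seg - seg.mean(axis=1, keepdims=True)) ** 2
    records = records.copy()
    records["prestim_power"] = power.mean(axis=1)
    flagged = np.zeros(len(records), dtype=bool)
    for subj in pd.unique(trials.subjects):
        rows = np.flatnonzero(trials.subjects == subj)
        pool = power[rows].ravel()
        q75, q25 = np.percentile(pool, [75, 25])
        limit = q75 + 3.0 * (q75 - q25)
        frac = (power[rows] > limit).mean(axis=1)
        flagged[rows] = frac > 0.5
    _flag(records, flagged, "prestim_emg")
    return records


def template_correlation_filter(records: pd.DataFrame, trials: TrialSet,
                                r_min: float = 0.40,
                                window: tuple[float, float] = MEP_WINDOW
                                ) -> pd.DataFrame:
    """Flag trials whose MEP waveform correlates poorly with the subject's
    mean MEP waveform (single pass; the template comes from trials not yet
    excluded)."""
    records = records.copy()
    seg = trials.emg[:, trials.time_mask(*window)]
    excluded = records["excluded"].to_numpy()
    r = np.full(len(records), np.nan)
    degenerate = np.zeros(len(records), dtype=bool)
    low = np.zeros(len(records), dtype=bool)
    for subj in pd.unique(trials.subjects):
        rows = np.flatnonzero(trials.subjects == subj)
        keep = rows[~excluded[rows]]
        if keep.size < 2:
            raise ValueError(
                f"subject {subj}: need >= 2 retained trials for a template")
        template = seg[keep].mean(axis=0)
        tc = template - template.mean()
        t_norm = np.sqrt((tc ** 2).sum())
        for i in rows:
            x = seg[i] - seg[i].mean()
            x_norm = np.sqrt((x ** 2).sum())
            if x_norm == 0 or t_norm == 0:
                degenerate[i] = True
                continue
            r[i] = float(x @ tc / (x_norm * t_norm))
            low[i] = r[i] <= r_min
    records["template_r"] = r
    _flag(records, degenerate, "degenerate")
    _flag(records, low, "template_r")
    return records


def log_transform(records: pd.DataFrame) -> pd.DataFrame:
    """Natural log of the peak-to-peak amplitudes (reduces right skew).

    Zero amplitudes are flagged rather than transformed."""
    records = records.copy()
    amp = records["peak_to_peak_mv"].to_numpy(dtype=float)
    _flag(records, amp <= 0, "zero_amplitude")
    ok = amp > 0
    records.loc[ok, "log_amplitude"] = np.log(amp[ok])
    return records


def process_emg(trials: TrialSet, r_min: float = 0.40) -> pd.DataFrame:
    """Full EMG stage: amplitude extraction, both exclusion filters (in the
    order pre-stimulus -> template), then the log transform."""
    records = _records_skeleton(trials)
    records = prestim_emg_filter(records, trials)
    records = template_correlation_filter(records, trials, r_min=r_min)
    return log_transform(records)
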