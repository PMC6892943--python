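"""Beta-event detection and morphological characterization.

A beta event is a maximal contiguous run of normalized beta-power samples
strictly above a per-subject percentile threshold, lasting at least 1.5
oscillatory cycles at the subject's individual beta frequency.  For every
event we record its maximum amplitude (normalized power units), the time of
that maximum, and its duration — the time during which power exceeds half of
the event's maximum, measured with linear interpolation between samples.

Runs touching a boundary of the analysis window count as events only when
their power maximum is interior (power already declining at the edge); the
duration of such edge events is estimated as twice the half-max time on the
side of the peak that lies fully inside the window.

Per-trial summaries follow the convention that, with several events in a
trial, the characteristics of the last event before the stimulus enter the
statistical models, and the event's timing is the latency of its power peak
before the stimulus (positive seconds; larger = earlier).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import BetaSeries

__all__ = [
    "EventConfig",
    "BetaEvent",
    "threshold_value",
    "detect_events",
    "event_duration",
    "time_above_level",
    "summarize_trial",
    "extract_metrics",
    "empirical_threshold",
]


@dataclass
class EventConfig:
    threshold_percentile: float = 75.0
    min_cycles: float = 1.5

    def validate(self) -> None:
        if not 50.0 <= self.threshold_percentile <= 98.0:
            raise ValueError("threshold percentile must be in [50, 98]")
        if self.min_cycles <= 0:
            raise ValueError("min_cycles must be positive")


@dataclass
class BetaEvent:
    onset_s: float
    offset_s: float
    peak_time_s: float
    max_amplitude: float
    duration_s: float
    is_edge: bool
    i0: int = 0          # run sample bounds within the analysis window
    i1: int = 0


def threshold_value(series, percentile: float):
    """Empirical percentile of the pooled normalized-power samples.

    For a :class:`BetaSeries`, pools all window samples across each subject's
    retained trials and returns a dict subject -> threshold; for a plain
    array, returns the percentile of its values.  Linear interpolation
    between order statistics.
    """
    if isinstance(series, BetaSeries):
        out = {}
        for subj in pd.unique(series.subjects):
            rows = series.subject_rows(subj)
            if rows.size == 0:
                raise ValueError(f"empty sample pool for subject {subj}")
            out[subj] = float(
                np.percentile(series.power[rows].ravel(), percentile))
        return out
    pool = np.asarray(series, dtype=float).ravel()
    if pool.size == 0:
        raise ValueError("empty sample pool")
    return float(np.percentile(pool, percentile))


def time_above_level(profile, dt: float, level: float,
                     extend_ends: bool = False) -> float:
    """Total time a piecewise-linear profile exceeds `level`.

    Crossing times are linearly interpolated between samples.  With
    ``extend_ends`` a supra-level boundary sample contributes an extra half
    sample step (the profile is treated as a sequence of dt-wide bins);
    without it, the measure is confined to [t_first, t_last].
    """
    p = np.asarray(profile, dtype=float)
    if p.size == 0:
        return 0.0
    if p.size == 1:
        return dt if (extend_ends and p[0] > level) else 0.0
    total = 0.0
    a, b = p[:-1], p[1:]
    both = (a > level) & (b > level)
    total += dt * np.count_nonzero(both)
    rising = (a <= level) & (b > level)
    falling = (a > level) & (b <= level)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_r = (b - level) / (b - a)
        frac_f = (a - level) / (a - b)
    total += dt * float(np.nansum(frac_r[rising]))
    total += dt * float(np.nansum(frac_f[falling]))
    if extend_ends:
        total += (dt / 2) * ((p[0] > level) + (p[-1] > level))
    return total


def event_duration(profile, dt: float) -> float:
    """Half-max duration of a standalone event power profile.

    Time during which the profile exceeds half of its maximum, with linear
    interpolation; supra-half boundary samples count as half a sample step.
    """
    p = np.asarray(profile, dtype=float)
    return time_above_level(p, dt, p.max() / 2.0, extend_ends=True)


def detect_events(power, times, threshold: float, ibf: float,
                  min_cycles: float = 1.5) -> list[BetaEvent]:
    """Detect beta events in one trial's normalized power series.

    Maximal runs of samples strictly above `threshold`; runs shorter than
    ``min_cycles / ibf`` seconds are discarded; edge runs survive only with
    an interior power maximum and get the doubled one-sided duration.
    """
    p = np.asarray(power, dtype=float)
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite power values")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dt = float(np.mean(np.diff(t)))
    above = p > threshold
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, p.size - 1]

    min_dur = min_cycles / ibf
    events: list[BetaEvent] = []
    for i0, i1 in zip(starts, ends):
        if (i1 - i0 + 1) * dt < min_dur - 1e-12:
            continue
        run = p[i0:i1 + 1]
        pk = i0 + int(np.argmax(run))
        touches_start = i0 == 0
        touches_end = i1 == p.size - 1
        is_edge = touches_start or touches_end
        if (touches_end and pk == i1) or (touches_start and pk == i0):
            continue  # power not declining at the window edge
        half = p[pk] / 2.0
        if touches_end:
            dur = 2.0 * time_above_level(p[i0:pk + 1], dt, half)
        elif touches_start:
            dur = 2.0 * time_above_level(p[pk:i1 + 1], dt, half)
        else:
            dur = time_above_level(run, dt, half)
        events.append(BetaEvent(
            onset_s=float(t[i0]), offset_s=float(t[i1]),
            peak_time_s=float(t[pk]), max_amplitude=float(p[pk]),
            duration_s=float(dur), is_edge=bool(is_edge),
            i0=int(i0), i1=int(i1)))
    return events


def summarize_trial(events: list[BetaEvent], power, times) -> dict:
    """Per-trial metric row: event count/presence, last-event morphology and
    peak latency before the stimulus, and mean normalized power over the
    full window (events or not)."""
    p = np.asarray(power, dtype=float)
    row = {
        "event_present": int(len(events) > 0),
        "n_events": len(events),
        "last_duration_s": np.nan,
        "last_amplitude": np.nan,
        "last_timing_s": np.nan,
        "mean_power": float(p.mean()),
    }
    if events:
        last = max(events, key=lambda e: e.peak_time_s)
        row["last_duration_s"] = last.duration_s
        row["last_amplitude"] = last.max_amplitude
        row["last_timing_s"] = -last.peak_time_s
    return row


def extract_metrics(series: BetaSeries,
                    config: EventConfig | None = None) -> pd.DataFrame:
    """TrialMetrics table (without MEP columns) for one detection threshold."""
    config = config or EventConfig()
    config.validate()
    thr = threshold_value(series, config.threshold_percentile)
    rows = []
    for i in range(series.n_trials):
        subj = series.subjects[i]
        ev = detect_events(series.power[i], series.times, thr[subj],
                           series.ibf[subj], config.min_cycles)
        row = summarize_trial(ev, series.power[i], series.times)
        row.update(subject=subj, trial=int(series.trial_ids[i]))
        rows.append(row)
    cols = ["subject", "trial", "event_present", "n_events",
            "last_duration_s", "last_amplitude", "last_timing_s",
            "mean_power"]
    return pd.DataFrame(rows)[cols]


def empirical_threshold(series: BetaSeries,
                        percentiles=None,
                        min_cycles: float = 1.5):
    """Data-driven event threshold.

    For each candidate percentile and subject, the Pearson correlation across
    trials between the fraction of window samples falling inside detected
    events and the trial's mean beta power; returns the percentile at which
    the subject-mean correlation curve peaks, together with the full curve
    (DataFrame: percentile, one column per subject, mean).
    """
    if percentiles is None:
        percentiles = np.arange(50.0, 99.0, 1.0)
    percentiles = np.asarray(percentiles, dtype=float)
    subjects = list(pd.unique(series.subjects))
    if len(subjects) < 2:
        raise ValueError("empirical threshold needs >= 2 subjects")
    n_win = series.power.shape[1]

    curve = np.full((percentiles.size, len(subjects)), np.nan)
    for j, subj in enumerate(subjects):
        rows = series.subject_rows(subj)
        if rows.size < 3:
            raise ValueError(f"subject {subj} has < 3 trials")
        mean_power = series.power[rows].mean(axis=1)
        pool = series.power[rows].ravel()
        thr_all = np.percentile(pool, percentiles)
        for k, thr in enumerate(thr_all):
            frac = np.empty(rows.size)
            for r, i in enumerate(rows):
                ev = detect_events(series.power[i], series.times, thr,
                                   series.ibf[subj], min_cycles)
                frac[r] = sum(e.i1 - e.i0 + 1 for e in ev) / n_win
            if frac.std() == 0 or mean_power.std() == 0:
                warnings.warn(
                    f"zero variance for subject {subj} at percentile "
                    f"{percentiles[k]:g}; excluded from the mean",
                    stacklevel=2)
                continue
            curve[k, j] = np.corrcoef(frac, mean_power)[0, 1]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_curve = np.nanmean(curve, axis=1)
    best = float(percentiles[int(np.nanargmax(mean_curve))])
    out = pd.DataFrame(curve, columns=subjects)
    out.insert(0, "percentile", percentiles)
    out["mean"] = mean_curve
    return best, out
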