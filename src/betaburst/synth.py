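"""Ground-truth-annotated synthetic EEG/EMG trial sets.

The generator emulates the statistical structure the downstream analysis
assumes: 32-channel stimulus-locked EEG epochs at 5 kHz in which the channel
over the contralateral motor cortex (C4) carries transient beta bursts —
amplitude-modulated sinusoids at the subject's individual beta frequency (IBF)
riding on 1/f background noise — and single-channel EMG epochs containing one
motor-evoked potential (MEP) per trial whose log peak-to-peak amplitude is a
linear function of the injected (ground-truth) beta metrics plus a per-subject
random intercept and Gaussian noise.

Three entry points, all driven by one :class:`SynthConfig`:

``generate_trialset``
    full raw-waveform trial set (EEG + EMG) plus :class:`GroundTruth`;
``simulate_metrics``
    the ground-truth per-trial metric table and log MEP amplitudes only
    (no waveforms) — the fast path for statistical parameter-recovery studies;
``simulate_power_series``
    normalized beta-power time series with injected burst profiles, bypassing
    the wavelet stage — the direct input for event-detector calibration.

Burst timing: the number of events per trial is Poisson(rate x window length)
and event peaks are uniform over the analysis window subject to a minimum
peak separation (events closer than a burst width are not identifiable as
separate events by any threshold detector).  The conditional placement uses
the exact spacings construction, so positions are uniform given the count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import TrialSet

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_trialset",
    "simulate_metrics",
    "simulate_power_series",
    "inject_artifacts",
    "METRIC_NAMES",
    "DEFAULT_CHANNELS",
]

METRIC_NAMES = (
    "event_present",
    "n_events",
    "last_duration_s",
    "last_amplitude",
    "last_timing_s",
    "mean_power",
)

# standard 10-20 montage, 32 channels, including the Hjorth set around C4
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]

# a Hann-squared power envelope has full width = half-max width / 0.36395
_HANN_POWER_FWHM = 2.0 * math.acos(2.0 ** -0.25) / math.pi  # = 0.363949...


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions: 20 subjects, 600 stimuli each,
    5 kHz sampling, 6 s epochs, beta events at 1.24/s lasting ~114 ms
    (half-max), IBFs inside 15-30 Hz, and log MEP amplitude coupled to mean
    beta power (b = 0.07) with subject random intercepts.
    """

    n_subjects: int = 20
    n_trials_per_subject: int = 600
    fs: float = 5000.0
    epoch_window: tuple[float, float] = (-3.0, 3.0)
    channels: tuple[str, ...] = tuple(DEFAULT_CHANNELS)

    ibf_range: tuple[float, float] = (16.0, 27.0)
    burst_rate: float = 1.24                  # events / s
    burst_duration_mean: float = 0.114        # s, half-max width of power env.
    burst_duration_sd: float = 0.015
    burst_amplitude_median_uv: float = 6.0    # lognormal median, uV
    burst_amplitude_sigma: float = 0.25       # lognormal log-sd
    min_peak_separation: float = 0.25         # s, hard core between peaks
    event_window: tuple[float, float] = (-1.0, -0.05)

    background_rms_uv: float = 8.0            # 1/f background per channel

    coupling: dict = field(default_factory=lambda: {"mean_power": 0.07})
    subject_intercept_sd: float = 0.3
    mep_noise_sd: float = 0.4                 # residual sd of log MEP
    mep_median_mv: float = 1.0
    mep_window: tuple[float, float] = (0.020, 0.040)
    emg_noise_rms_mv: float = 0.005
    emg_contamination_fraction: float = 0.0   # trials with voluntary EMG
    artifact_fraction: float = 0.0            # EEG artifact trials (pipeline)

    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo, hi = self.epoch_window
        if not (lo <= -1.0 and hi >= 0.05):
            raise ValueError("epoch must cover at least (-1, +0.05) s")
        if not (15.0 <= self.ibf_range[0] <= self.ibf_range[1] <= 30.0):
            raise ValueError("ibf_range must lie within 15-30 Hz")
        if self.burst_duration_mean < 1.5 / self.ibf_range[0]:
            raise ValueError(
                "burst_duration_mean must be >= 1.5 cycles at every IBF")
        bad = set(self.coupling) - set(METRIC_NAMES)
        if bad:
            raise ValueError(
                f"coupling references unknown metrics: {sorted(bad)}; "
                f"known metrics are {METRIC_NAMES}")

    @property
    def hjorth_channels(self) -> tuple[str, ...]:
        return ("C4", "FC2", "FC6", "CP2", "CP6")


@dataclass
class GroundTruth:
    """What the generator injected, for scoring every downstream stage."""

    subjects: pd.DataFrame   # subject, ibf, intercept
    events: pd.DataFrame     # subject, trial, onset_s, offset_s, peak_time_s,
    #                          peak_amplitude, duration_s
    trials: pd.DataFrame     # subject, trial, metric columns, log_mep, flags
    coupling: dict

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(d / "gt_subjects.tsv", sep="\t", index=False)
        self.events.to_csv(d / "gt_events.tsv", sep="\t", index=False)
        self.trials.to_csv(d / "gt_trials.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# ground-truth sampling (shared by all three entry points)
# --------------------------------------------------------------------------

def _place_peaks(rng, n, window, sep):
    """n peak times, uniform over `window` given pairwise separation >= sep.

    Uses the spacings construction: shrink the window by (n-1)*sep, drop n
    sorted uniforms, then re-inflate.  Returns fewer than n peaks only when n
    exceeds the packing limit of the window.
    """
    lo, hi = window
    width = hi - lo
    n_max = int(width // sep) + 1 if sep > 0 else n
    n = min(n, n_max)
    if n == 0:
        return np.empty(0)
    slack = width - (n - 1) * sep
    x = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + x + sep * np.arange(n)


def _hann_power_integral(t0, t1, T):
    """Integral of cos^4(pi t / T) over [t0, t1] (support |t| <= T/2)."""
    a, b = np.clip([t0, t1], -T / 2, T / 2)
    w = math.pi / T

    def F(t):
        u = w * t
        return (3 * u / 8 + math.sin(2 * u) / 4 + math.sin(4 * u) / 32) / w

    return max(F(b) - F(a), 0.0)


def _draw_ground_truth(config: SynthConfig):
    """Sample subjects, per-trial events and the coupled log MEP amplitudes."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))

    subj_names = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    ibfs = rng.uniform(*config.ibf_range, size=config.n_subjects)
    intercepts = rng.normal(0.0, config.subject_intercept_sd,
                            size=config.n_subjects)
    subjects = pd.DataFrame(
        {"subject": subj_names, "ibf": ibfs, "intercept": intercepts})

    win = config.event_window
    width = win[1] - win[0]
    # events occur throughout the pre-stimulus period (as in resting EEG);
    # metrics and counts are taken from events peaking inside the analysis
    # window, which remain Poisson(rate x window length)
    inject = (config.epoch_window[0], 0.0)
    lam = config.burst_rate * (inject[1] - inject[0])

    ev_rows, tr_rows = [], []
    trial_id = 0
    for s_idx, subj in enumerate(subj_names):
        ibf = ibfs[s_idx]
        min_dur = 1.5 / ibf
        for _ in range(config.n_trials_per_subject):
            n = int(rng.poisson(lam))
            peaks = _place_peaks(rng, n, inject, config.min_peak_separation)
            n = peaks.size
            durs = np.clip(
                rng.normal(config.burst_duration_mean,
                           config.burst_duration_sd, size=n),
                min_dur, None)
            amps = config.burst_amplitude_median_uv * np.exp(
                rng.normal(0.0, config.burst_amplitude_sigma, size=n))
            phases = rng.uniform(0.0, 2 * math.pi, size=n)
            for k in range(n):
                T = durs[k] / _HANN_POWER_FWHM
                ev_rows.append({
                    "subject": subj, "trial": trial_id,
                    "onset_s": peaks[k] - T / 2, "offset_s": peaks[k] + T / 2,
                    "peak_time_s": peaks[k], "amplitude_uv": amps[k],
                    "duration_s": durs[k], "phase": phases[k],
                })
            # mean injected beta power over the window (peak envelope power
            # of one burst of amplitude a is a^2; background excluded)
            mp_raw = 0.0
            for k in range(n):
                T = durs[k] / _HANN_POWER_FWHM
                mp_raw += amps[k] ** 2 * _hann_power_integral(
                    win[0] - peaks[k], win[1] - peaks[k], T)
            mp_raw /= width
            in_win = np.flatnonzero((peaks >= win[0]) & (peaks <= win[1]))
            n_win = in_win.size
            row = {"subject": subj, "trial": trial_id,
                   "event_present": int(n_win > 0), "n_events": n_win,
                   "_mean_power_raw": mp_raw}
            if n_win > 0:
                last = in_win[int(np.argmax(peaks[in_win]))]
                row["last_duration_s"] = durs[last]
                row["_last_amp_raw"] = amps[last] ** 2
                row["last_timing_s"] = -peaks[last]
            else:
                row["last_duration_s"] = np.nan
                row["_last_amp_raw"] = np.nan
                row["last_timing_s"] = np.nan
            tr_rows.append(row)
            trial_id += 1

    trials = pd.DataFrame(tr_rows)
    events = pd.DataFrame(
        ev_rows, columns=["subject", "trial", "onset_s", "offset_s",
                          "peak_time_s", "amplitude_uv", "duration_s",
                          "phase"])

    # normalize power-scaled metrics per subject (mirrors the analysis-side
    # convention: divide by the subject's mean pre-stimulus beta power)
    norm = trials.groupby("subject")["_mean_power_raw"].transform("mean")
    with np.errstate(invalid="ignore", divide="ignore"):
        trials["mean_power"] = np.where(
            norm > 0, trials["_mean_power_raw"] / norm, 0.0)
        trials["last_amplitude"] = trials["_last_amp_raw"] / norm.where(
            norm > 0)
    trials = trials.drop(columns=["_mean_power_raw", "_last_amp_raw"])

    # log MEP amplitude: intercept + sum of couplings x metrics + noise.
    # Event-conditional metrics contribute 0 on trials without events.
    log_mep = (math.log(config.mep_median_mv)
               + trials["subject"].map(
                   dict(zip(subj_names, intercepts))).to_numpy())
    for name, b in config.coupling.items():
        x = trials[name].to_numpy(dtype=float)
        log_mep = log_mep + b * np.nan_to_num(x, nan=0.0)
    log_mep = log_mep + rng.normal(0.0, config.mep_noise_sd,
                                   size=len(trials))
    trials["log_mep"] = log_mep

    n_contam = int(round(config.emg_contamination_fraction * len(trials)))
    contam = np.zeros(len(trials), dtype=bool)
    if n_contam:
        contam[rng.permutation(len(trials))[:n_contam]] = True
    trials["emg_contaminated"] = contam

    return GroundTruth(subjects=subjects, events=events, trials=trials,
                       coupling=dict(config.coupling))


def simulate_metrics(config: SynthConfig) -> pd.DataFrame:
    """Ground-truth per-trial metric table with log MEP amplitudes.

    Identical sampling stream to :func:`generate_trialset`, without waveform
    synthesis — use for parameter-recovery and calibration studies where the
    signal-processing stages are not under test.
    """
    return _draw_ground_truth(config).trials.copy()


# --------------------------------------------------------------------------
# waveform synthesis
# --------------------------------------------------------------------------

def _one_over_f_noise(rng, n_series, n_times, fs, rms):
    """Rows of 1/f (power) noise with the requested RMS."""
    white = rng.standard_normal((n_series, n_times))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_times, d=1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, 1.0))  # flat below 1 Hz
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n_times, axis=-1)
    scale = rms / np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x * scale


def _mep_template(times, window, fs):
    """Fixed biphasic MEP waveform, unit peak-to-peak, inside `window`."""
    t0, t1 = window
    w = np.zeros_like(times)
    m = (times >= t0) & (times <= t1)
    tau = (times[m] - t0) / (t1 - t0)          # 0..1 across the window
    w[m] = np.sin(2 * math.pi * 2.0 * tau) * np.sin(math.pi * tau) ** 2
    ptp = w.max() - w.min()
    return w / ptp


def generate_trialset(config: SynthConfig) -> tuple[TrialSet, GroundTruth]:
    """Synthesize the full raw trial set described by `config`."""
    gt = _draw_ground_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))

    fs = config.fs
    lo, hi = config.epoch_window
    n_times = int(round((hi - lo) * fs)) + 1
    times = lo + np.arange(n_times) / fs
    channels = list(config.channels)
    for ch in config.hjorth_channels:
        if ch not in channels:
            raise ValueError(f"channel list must include {ch}")
    n_trials = len(gt.trials)
    c4 = channels.index("C4")

    eeg = np.empty((n_trials, len(channels), n_times), dtype=np.float32)
    for tr in range(n_trials):  # chunked to bound memory at 5 kHz
        eeg[tr] = _one_over_f_noise(rng, len(channels), n_times, fs,
                                    config.background_rms_uv)

    ibf_map = dict(zip(gt.subjects["subject"], gt.subjects["ibf"]))
    for row in gt.events.itertuples(index=False):
        ibf = ibf_map[row.subject]
        T = row.duration_s / _HANN_POWER_FWHM
        i0 = max(int(math.ceil((row.peak_time_s - T / 2 - lo) * fs)), 0)
        i1 = min(int(math.floor((row.peak_time_s + T / 2 - lo) * fs)),
                 n_times - 1)
        t = times[i0:i1 + 1] - row.peak_time_s
        env = np.cos(math.pi * t / T) ** 2
        eeg[row.trial, c4, i0:i1 + 1] += (
            row.amplitude_uv * env * np.sin(2 * math.pi * ibf * t + row.phase)
        ).astype(np.float32)

    template = _mep_template(times, config.mep_window, fs)
    emg = rng.standard_normal((n_trials, n_times)).astype(np.float32)
    emg *= config.emg_noise_rms_mv
    amp_mv = np.exp(gt.trials["log_mep"].to_numpy())
    emg += (amp_mv[:, None] * template[None, :]).astype(np.float32)
    contam = gt.trials["emg_contaminated"].to_numpy()
    if contam.any():
        emg[contam] += 0.3 * rng.standard_normal(
            (int(contam.sum()), n_times)).astype(np.float32)

    trials = TrialSet(
        eeg=eeg, emg=emg, times=times, fs=fs, channels=channels,
        subjects=gt.trials["subject"].to_numpy(),
        trial_ids=gt.trials["trial"].to_numpy(),
    )
    return trials, gt


def inject_artifacts(trials: TrialSet, fraction: float, seed: int
                     ) -> tuple[TrialSet, np.ndarray]:
    """Contaminate round(fraction*n) trials with a >50 uV pre-stimulus
    transient on C4; returns the new trial set and the contaminated trial ids.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = trials.n_trials
    n_bad = int(round(fraction * n))
    idx = np.sort(rng.permutation(n)[:n_bad])
    out = replace(trials, eeg=trials.eeg.copy())
    c4 = out.channel_index("C4")
    width = 0.1
    for i in idx:
        center = rng.uniform(-0.9, -0.1)
        m = (out.times >= center - width / 2) & (out.times <= center + width / 2)
        pulse = 80.0 * np.sin(
            math.pi * (out.times[m] - center + width / 2) / width)
        out.eeg[i, c4, m] += pulse.astype(out.eeg.dtype)
    return out, trials.trial_ids[idx]


# --------------------------------------------------------------------------
# direct power-series mode
# --------------------------------------------------------------------------

def simulate_power_series(
    n_trials: int,
    *,
    rate: float = 1.24,
    duration_mean: float = 0.114,
    duration_sd: float = 0.015,
    window: tuple[float, float] = (-1.0, -0.05),
    fs: float = 5000.0,
    background_level: float = 0.3,
    background_sd: float = 0.08,
    background_smooth_s: float = 0.05,
    peak_power_median: float = 4.0,
    peak_power_sigma: float = 0.2,
    min_separation: float = 0.25,
    seed: int = 0,
):
    """Normalized-beta-power-like series with injected Hann-squared bursts.

    Bypasses the raw-EEG and wavelet stages: background is smooth positive
    noise around `background_level` and each burst contributes a Hann-squared
    power profile whose half-max width is the drawn duration.  Returns
    ``(power [trial x time], times, events DataFrame)``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = window
    n_t = int(round((hi - lo) * fs)) + 1
    times = lo + np.arange(n_t) / fs
    width = hi - lo
    lam = rate * width

    k = max(int(round(background_smooth_s * fs)), 1)
    noise = rng.standard_normal((n_trials, n_t + k - 1))
    smooth = np.cumsum(noise, axis=-1, dtype=float)
    smooth = (smooth[:, k - 1:] - np.concatenate(
        [np.zeros((n_trials, 1)), smooth[:, :n_t - 1]], axis=-1)) / k
    smooth *= background_sd / smooth.std()
    power = np.clip(background_level + smooth, 0.0, None)

    rows = []
    for tr in range(n_trials):
        n = int(rng.poisson(lam))
        peaks = _place_peaks(rng, n, window, min_separation)
        durs = np.clip(rng.normal(duration_mean, duration_sd, peaks.size),
                       0.02, None)
        pk = peak_power_median * np.exp(
            rng.normal(0.0, peak_power_sigma, peaks.size))
        for p, d, a in zip(peaks, durs, pk):
            T = d / _HANN_POWER_FWHM
            m = np.abs(times - p) <= T / 2
            power[tr, m] += a * np.cos(math.pi * (times[m] - p) / T) ** 4
            rows.append({"trial": tr, "peak_time_s": p, "duration_s": d,
                         "peak_power": a})
    events = pd.DataFrame(
        rows, columns=["trial", "peak_time_s", "duration_s", "peak_power"])
    return power, times, events
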