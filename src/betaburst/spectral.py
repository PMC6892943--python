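"""Power spectra, individual beta frequency, and beta-power time series.

Per subject, a multitaper (Slepian-sequence) power spectral density of the
pre-stimulus data between 1 and 30 Hz, with +/-2 Hz spectral smoothing,
locates the individual beta frequency (IBF) as the argmax of power in the
15-30 Hz band.  Time-resolved beta power at the IBF comes from a 5-cycle
complex Morlet wavelet.  To avoid edge effects at the stimulus, each trial's
pre-stimulus segment is mirrored about the stimulus time before convolution,
then the squared magnitude is cropped to the analysis window (-1 to -0.05 s)
and divided by the subject's mean pre-stimulus beta power, so normalized
power is dimensionless with per-subject mean 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from mne.time_frequency import psd_array_multitaper, tfr_array_morlet

from .data import BetaSeries, TrialSet

__all__ = [
    "SpectralConfig",
    "estimate_psd",
    "find_ibf",
    "beta_power_series",
]


@dataclass
class SpectralConfig:
    psd_band: tuple[float, float] = (1.0, 30.0)
    smoothing_half_bw: float = 2.0     # Hz on each side of every frequency
    ibf_band: tuple[float, float] = (15.0, 30.0)
    wavelet_cycles: float = 5.0
    trial_window: tuple[float, float] = (-1.0, -0.05)

    def validate(self) -> None:
        if not (self.psd_band[0] <= self.ibf_band[0]
                < self.ibf_band[1] <= self.psd_band[1]):
            raise ValueError("ibf_band must lie inside psd_band")
        if self.wavelet_cycles < 3:
            raise ValueError("wavelet_cycles must be >= 3")
        if self.trial_window[1] >= 0:
            raise ValueError("trial window must be strictly pre-stimulus")


def _prestim(trials: TrialSet) -> np.ndarray:
    """Single-channel pre-stimulus segment [trial x time], t < 0."""
    if len(trials.channels) != 1:
        raise ValueError("expected a single-channel (Hjorth) trial set")
    m = trials.times < 0
    return trials.eeg[:, 0, m]


def estimate_psd(trials: TrialSet, config: SpectralConfig | None = None
                 ) -> pd.DataFrame:
    """Per-subject multitaper PSD of the pre-stimulus data, averaged over
    trials.  Returns a DataFrame indexed by frequency (Hz), one column per
    subject."""
    config = config or SpectralConfig()
    config.validate()
    seg = _prestim(trials)
    if seg.shape[1] < trials.fs:
        raise ValueError("need >= 1 s of pre-stimulus data for the PSD")
    psd, freqs = psd_array_multitaper(
        seg, sfreq=trials.fs,
        fmin=config.psd_band[0], fmax=config.psd_band[1],
        bandwidth=2.0 * config.smoothing_half_bw,
        normalization="full", verbose="error")
    out = {}
    for subj in pd.unique(trials.subjects):
        out[subj] = psd[trials.subjects == subj].mean(axis=0)
    return pd.DataFrame(out, index=pd.Index(freqs, name="frequency_hz"))


def find_ibf(spectrum: pd.Series | pd.DataFrame,
             band: tuple[float, float] = (15.0, 30.0)):
    """Individual beta frequency: argmax of spectral power inside `band`.

    Accepts one subject's spectrum (Series indexed by frequency) or a
    DataFrame of spectra (returns a dict subject -> Hz).  An argmax sitting
    on a band edge triggers a "no interior peak" warning but the frequency is
    still returned.
    """
    if isinstance(spectrum, pd.DataFrame):
        return {c: find_ibf(spectrum[c], band) for c in spectrum.columns}
    freqs = spectrum.index.to_numpy(dtype=float)
    m = (freqs >= band[0]) & (freqs <= band[1])
    if not m.any():
        raise ValueError("spectrum does not cover the requested band")
    sub = spectrum.to_numpy()[m]
    f_band = freqs[m]
    i = int(np.argmax(sub))
    if i in (0, sub.size - 1):
        warnings.warn(
            f"no interior spectral peak in {band} Hz; argmax at band edge "
            f"{f_band[i]:g} Hz", stacklevel=2)
    return float(f_band[i])


def _mirrored(seg: np.ndarray) -> np.ndarray:
    """Time-reversed reflection of the pre-stimulus segment about t = 0."""
    return np.concatenate([seg, seg[..., ::-1]], axis=-1)


def beta_power_series(
    trials: TrialSet,
    ibf,
    config: SpectralConfig | None = None,
    *,
    pad_mode: str = "mirror",
) -> BetaSeries:
    """Normalized beta-power time series at the subject IBF.

    `ibf` is a mapping subject -> Hz (or a single float applied to all).
    ``pad_mode="zero"`` replaces the mirrored extension with zero padding of
    the same length (diagnostic only; the analysis uses mirroring).
    """
    config = config or SpectralConfig()
    config.validate()
    ibf_map = (dict(ibf) if hasattr(ibf, "keys")
               else {s: float(ibf) for s in pd.unique(trials.subjects)})
    for s, f in ibf_map.items():
        if not 15.0 <= f <= 30.0:
            raise ValueError(f"IBF {f} Hz for {s} outside 15-30 Hz")

    seg = _prestim(trials)
    n_pre = seg.shape[1]
    t_pre = trials.times[trials.times < 0]
    t_full = t_pre[0] + np.arange(2 * n_pre) / trials.fs
    w0, w1 = config.trial_window
    eps = 0.5 / trials.fs
    win = (t_full >= w0 - eps) & (t_full <= w1 + eps)

    power = np.empty((trials.n_trials, int(win.sum())))
    norm_const: dict = {}
    for subj in pd.unique(trials.subjects):
        rows = np.flatnonzero(trials.subjects == subj)
        if pad_mode == "mirror":
            ext = _mirrored(seg[rows])
        elif pad_mode == "zero":
            ext = np.concatenate(
                [seg[rows], np.zeros_like(seg[rows])], axis=-1)
        else:
            raise ValueError("pad_mode must be 'mirror' or 'zero'")
        tfr = tfr_array_morlet(
            ext[:, None, :], sfreq=trials.fs,
            freqs=[ibf_map[subj]], n_cycles=config.wavelet_cycles,
            output="power", verbose="error")
        p = tfr[:, 0, 0, win]
        norm = float(p.mean())
        if norm == 0.0:
            raise ZeroDivisionError(
                f"zero beta power for subject {subj}: cannot normalize")
        power[rows] = p / norm
        norm_const[subj] = norm

    return BetaSeries(
        power=power, times=t_full[win], fs=trials.fs,
        subjects=trials.subjects.copy(), trial_ids=trials.trial_ids.copy(),
        ibf=dict(ibf_map), norm_constant=norm_const)
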