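"""In-memory and on-disk containers for epoched EEG/EMG trial data.

A :class:`TrialSet` holds stimulus-locked epochs (stimulus at t = 0) for all
subjects of a study: EEG as ``[trial x channel x time]`` in microvolts and EMG
as ``[trial x time]`` in millivolts, plus the per-trial subject labels that the
mixed-effects stage needs.  Serialization uses a single self-describing HDF5
container so that every pipeline stage can be run from the shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = ["TrialSet", "BetaSeries"]


@dataclass
class TrialSet:
    """Epoched multi-channel EEG plus single-channel EMG.

    Attributes
    ----------
    eeg : ndarray, shape (n_trials, n_channels, n_times)
        EEG voltage in microvolts.
    emg : ndarray, shape (n_trials, n_times)
        EMG voltage in millivolts (same time axis as the EEG).
    times : ndarray, shape (n_times,)
        Seconds relative to the stimulus; strictly increasing and spanning 0.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Unique channel names, one per EEG row.
    subjects : ndarray of str, shape (n_trials,)
        Subject label of each trial.
    trial_ids : ndarray of int, shape (n_trials,)
        Stable per-trial identifiers (survive sub-selection).
    """

    eeg: np.ndarray
    emg: np.ndarray
    times: np.ndarray
    fs: float
    channels: list[str]
    subjects: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        if self.eeg.ndim != 3:
            raise ValueError("eeg must be [trial x channel x time]")
        if len(self.channels) != len(set(self.channels)):
            raise ValueError("channel names must be unique")
        if self.eeg.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if self.eeg.shape[2] != self.times.size:
            raise ValueError("time axis mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.times[0] > 0 or self.times[-1] < 0:
            raise ValueError("epoch must cover the stimulus at t=0")

    @property
    def n_trials(self) -> int:
        return self.eeg.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as ``[trial x time]``."""
        return self.eeg[:, self.channel_index(name), :]

    def select(self, mask: np.ndarray) -> "TrialSet":
        """Sub-select trials by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return replace(
            self,
            eeg=self.eeg[mask],
            emg=self.emg[mask],
            subjects=self.subjects[mask],
            trial_ids=self.trial_ids[mask],
        )

    def time_mask(self, start: float, stop: float, *,
                  closed: str = "both") -> np.ndarray:
        """Boolean mask over the time axis for the interval [start, stop].

        ``closed`` is one of ``"both"``, ``"left"``, ``"right"`` and controls
        endpoint inclusion (a half-sample tolerance absorbs float grid error).
        """
        eps = 0.5 / self.fs
        left = self.times >= start - (eps if closed in ("both", "left") else -eps)
        right = self.times <= stop + (eps if closed in ("both", "right") else -eps)
        return left & right

    # ---------------------------------------------------------------- on disk
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("eeg", data=self.eeg.astype(np.float32),
                             compression="gzip", compression_opts=1)
            f.create_dataset("emg", data=self.emg.astype(np.float32),
                             compression="gzip", compression_opts=1)
            f.create_dataset("times", data=self.times)
            f.create_dataset("trial_ids", data=self.trial_ids)
            f.create_dataset(
                "subjects",
                data=np.array([str(s) for s in self.subjects], dtype="S32"))
            f.attrs["fs"] = self.fs
            f.attrs["channels"] = [str(c) for c in self.channels]

    @classmethod
    def load(cls, path) -> "TrialSet":
        with h5py.File(path, "r") as f:
            return cls(
                eeg=f["eeg"][...].astype(float),
                emg=f["emg"][...].astype(float),
                times=f["times"][...],
                fs=float(f.attrs["fs"]),
                channels=[str(c) for c in f.attrs["channels"]],
                subjects=np.array([s.decode() for s in f["subjects"][...]],
                                  dtype=object),
                trial_ids=f["trial_ids"][...],
            )


@dataclass
class BetaSeries:
    """Per-trial normalized beta-power time series at the subject IBF.

    ``power`` is ``[trial x time]`` over the pre-stimulus analysis window,
    already divided by the subject's normalization constant (mean raw power
    over that subject's retained trials and window samples), so the grand mean
    of each subject's rows is 1.
    """

    power: np.ndarray
    times: np.ndarray
    fs: float
    subjects: np.ndarray
    trial_ids: np.ndarray
    ibf: dict = field(default_factory=dict)            # subject -> Hz
    norm_constant: dict = field(default_factory=dict)  # subject -> raw power

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def subject_rows(self, subject) -> np.ndarray:
        return np.flatnonzero(self.subjects == subject)

    def save(self, path) -> None:
        subj = sorted(self.ibf)
        with h5py.File(path, "w") as f:
            f.create_dataset("power", data=self.power.astype(np.float32),
                             compression="gzip", compression_opts=1)
            f.create_dataset("times", data=self.times)
            f.create_dataset("trial_ids", data=self.trial_ids)
            f.create_dataset(
                "subjects",
                data=np.array([str(s) for s in self.subjects], dtype="S32"))
            f.attrs["fs"] = self.fs
            f.attrs["ibf_subjects"] = [str(s) for s in subj]
            f.attrs["ibf_values"] = [float(self.ibf[s]) for s in subj]
            f.attrs["norm_values"] = [float(self.norm_constant[s]) for s in subj]

    @classmethod
    def load(cls, path) -> "BetaSeries":
        with h5py.File(path, "r") as f:
            subj = [str(s) for s in f.attrs["ibf_subjects"]]
            return cls(
                power=f["power"][...].astype(float),
                times=f["times"][...],
                fs=float(f.attrs["fs"]),
                subjects=np.array([s.decode() for s in f["subjects"][...]],
                                  dtype=object),
                trial_ids=f["trial_ids"][...],
                ibf=dict(zip(subj, f.attrs["ibf_values"])),
                norm_constant=dict(zip(subj, f.attrs["norm_values"])),
            )
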