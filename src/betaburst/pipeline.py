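"""End-to-end orchestration of the synthetic beta-event -> MEP study.

``run_all`` executes simulate -> EMG processing -> common average reference
-> Hjorth transform -> artifact rejection -> PSD / IBF -> wavelet beta power
-> event detection (once per threshold) -> mixed-effects fits,
cross-validation and likelihood-ratio model comparison, and returns a result
bundle with a Table-1-style report per detection threshold.  Identical
config + seed gives an identical bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import emg as emg_mod
from . import events as events_mod
from . import preprocess, spectral, stats
from .synth import SynthConfig, generate_trialset, inject_artifacts

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger("betaburst")

#: metric -> (column, event-trials-only) fitted for each threshold
MODEL_PLAN = [
    ("event_present", "event_present", False),
    ("n_events", "n_events", True),
    ("last_duration_s", "last_duration_s", True),
    ("last_amplitude", "last_amplitude", True),
    ("last_timing_s", "last_timing_s", True),
    ("mean_power", "mean_power", True),
    ("mean_power_all", "mean_power", False),
]

LRT_CHARACTERISTICS = ["n_events", "last_duration_s", "last_amplitude",
                       "last_timing_s"]


@dataclass
class RunConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    spectral: spectral.SpectralConfig = field(
        default_factory=spectral.SpectralConfig)
    thresholds: tuple[float, ...] = (75.0, 82.0)
    min_cycles: float = 1.5
    cv_k: int = 10
    cv_seed: int = 0
    cv_alpha: float = 0.05      # CV only for metrics significant at this level
    out: str | None = None

    def validate(self) -> None:
        if not self.thresholds:
            raise ValueError("thresholds list must be non-empty")
        self.synth.validate()
        self.spectral.validate()
        for p in self.thresholds:
            events_mod.EventConfig(p, self.min_cycles).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        synth_kw = doc.get("synth", {})
        for key in ("epoch_window", "ibf_range", "event_window",
                    "mep_window", "channels"):
            if key in synth_kw and isinstance(synth_kw[key], list):
                synth_kw[key] = tuple(synth_kw[key])
        spec_kw = doc.get("spectral", {})
        for key in ("psd_band", "ibf_band", "trial_window"):
            if key in spec_kw and isinstance(spec_kw[key], list):
                spec_kw[key] = tuple(spec_kw[key])
        ev = doc.get("events", {})
        st = doc.get("stats", {})
        return cls(
            synth=SynthConfig(**synth_kw),
            spectral=spectral.SpectralConfig(**spec_kw),
            thresholds=tuple(ev.get("thresholds", (75.0, 82.0))),
            min_cycles=ev.get("min_cycles", 1.5),
            cv_k=st.get("k", 10),
            cv_seed=st.get("seed", 0),
            out=doc.get("out"),
        )


def build_trial_metrics(series, emg_records: pd.DataFrame,
                        event_config) -> pd.DataFrame:
    """TrialMetrics table for one threshold: event metrics joined with the
    log MEP amplitudes and the union of exclusion flags."""
    metrics = events_mod.extract_metrics(series, event_config)
    emg_cols = emg_records[["trial", "log_amplitude", "excluded", "reason"]]
    merged = metrics.merge(emg_cols, on="trial", how="left", validate="1:1")
    merged = merged.rename(columns={"log_amplitude": "log_mep",
                                    "reason": "exclusion_reason"})
    merged["excluded"] = merged["excluded"].fillna(False).astype(bool)
    merged["exclusion_reason"] = merged["exclusion_reason"].fillna("")
    return merged


def _fit_table(table: pd.DataFrame, threshold_label: str,
               cv_k: int, cv_seed: int, cv_alpha: float) -> pd.DataFrame:
    rows = []
    for label, column, event_only in MODEL_PLAN:
        res = stats.MEPModel(table, column,
                             event_trials_only=event_only).fit()
        pct = res.percent_change.loc[column]
        row = {
            "threshold": threshold_label,
            "metric": label,
            "trial_filter": "event" if event_only else "all",
            "n": res.nobs,
            "estimate": res.params[column],
            "ci_low": res.conf_int_.loc[column, "ci_low"],
            "ci_high": res.conf_int_.loc[column, "ci_high"],
            "p": res.pvalues[column],
            "aic": res.aic,
            "percent_change": round(pct["percent"], 2),
            "pct_ci_low": round(pct["ci_low"], 2),
            "pct_ci_high": round(pct["ci_high"], 2),
            "cv_rho": np.nan,
            "cv_nrmse": np.nan,
            "ols_fallback": res.fallback_ols,
        }
        if row["p"] < cv_alpha or label.startswith("mean_power"):
            cv = res.cross_validate(k=cv_k, seed=cv_seed)
            row["cv_rho"] = cv.mean_rho
            row["cv_nrmse"] = cv.nrmse
        rows.append(row)
    return pd.DataFrame(rows)


def _lrt_table(table: pd.DataFrame, threshold_label: str) -> pd.DataFrame:
    """Does any event characteristic add predictive value beyond mean power?
    Compared on event trials, where both models are defined."""
    simple = stats.MEPModel(table, "mean_power",
                            event_trials_only=True).fit()
    rows = []
    for char in LRT_CHARACTERISTICS:
        full = stats.MEPModel(table, ["mean_power", char],
                              event_trials_only=True).fit()
        lrt = stats.likelihood_ratio_test(simple, full)
        rows.append({"threshold": threshold_label, "added_metric": char,
                     "lrt_statistic": lrt.statistic, "df": lrt.df,
                     "p": lrt.pvalue})
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Run the full synthetic study; returns a result bundle dict with keys
    ``report`` (Table-1-style rows per threshold), ``lrt``, ``correlations``,
    ``metrics`` (TrialMetrics per threshold), ``counts``, ``ibf``."""
    config.validate()
    counts: dict = {}

    log.info("simulate: %d subjects x %d trials", config.synth.n_subjects,
             config.synth.n_trials_per_subject)
    trials, gt = generate_trialset(config.synth)
    counts["n_generated"] = trials.n_trials
    if config.synth.artifact_fraction > 0:
        trials, contaminated = inject_artifacts(
            trials, config.synth.artifact_fraction,
            seed=int(config.synth.seed) + 7919)
        counts["n_artifact_injected"] = len(contaminated)

    emg_records = emg_mod.process_emg(trials)

    referenced = preprocess.common_average_reference(trials)
    hjorth = preprocess.hjorth_transform(referenced)
    retained, rejection = preprocess.reject_artifacts(hjorth)
    counts["n_eeg_rejected"] = int(rejection["rejected"].sum())
    log.info("artifact rejection: %d/%d trials retained",
             retained.n_trials, trials.n_trials)

    psd = spectral.estimate_psd(retained, config.spectral)
    ibf = spectral.find_ibf(psd, config.spectral.ibf_band)
    series = spectral.beta_power_series(retained, ibf, config.spectral)

    emg_retained = emg_records[emg_records["trial"].isin(retained.trial_ids)]
    counts["n_emg_excluded"] = int(emg_retained["excluded"].sum())
    counts["n_retained"] = (retained.n_trials
                            - counts["n_emg_excluded"])
    assert counts["n_generated"] == (counts["n_retained"]
                                     + counts["n_eeg_rejected"]
                                     + counts["n_emg_excluded"])

    report, lrt, metrics_by_thr = [], [], {}
    correlations = None
    for p in config.thresholds:
        label = f"{p:g}"
        ev_cfg = events_mod.EventConfig(p, config.min_cycles)
        table = build_trial_metrics(series, emg_records, ev_cfg)
        metrics_by_thr[label] = table
        report.append(_fit_table(table, label, config.cv_k, config.cv_seed,
                                 config.cv_alpha))
        lrt.append(_lrt_table(table, label))
        if correlations is None:
            _, correlations = stats.metric_power_correlations(table)

    bundle = {
        "report": pd.concat(report, ignore_index=True),
        "lrt": pd.concat(lrt, ignore_index=True),
        "correlations": correlations,
        "metrics": metrics_by_thr,
        "counts": counts,
        "ibf": ibf,
        "ground_truth": gt,
    }
    if config.out:
        out = Path(config.out)
        out.mkdir(parents=True, exist_ok=True)
        bundle["report"].to_csv(out / "report.tsv", sep="\t", index=False)
        bundle["lrt"].to_csv(out / "lrt.tsv", sep="\t", index=False)
        correlations.to_csv(out / "metric_power_correlations.tsv", sep="\t")
        for label, table in metrics_by_thr.items():
            table.to_csv(out / f"trial_metrics_p{label}.tsv", sep="\t",
                         index=False)
        pd.Series(counts).to_csv(out / "counts.tsv", sep="\t", header=False)
    return bundle
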