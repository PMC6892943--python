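"""Mixed-effects modeling of trial-by-trial beta-metric -> MEP relationships.

The core object is :class:`MEPModel`: log MEP amplitude regressed on one or
more beta metrics as fixed effects with a random intercept per subject,
always fit by maximum likelihood (so likelihood-ratio tests and AIC
comparisons between fits are valid).  :meth:`MEPModel.fit` returns a
:class:`MEPResults` carrying the estimates, Wald 95% confidence intervals,
p-values, AIC, and the back-transformed percent change in raw MEP amplitude
per unit metric, (e^b - 1) * 100.  Cross-validation (per-subject 90/10
splits, k = 10) and likelihood-ratio model comparison hang off these objects.

Event-conditional metrics (event count, last-event duration/amplitude/timing)
are modeled on trials containing at least one event; event presence and the
all-trials mean-power model use every retained trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "MEPModel",
    "MEPResults",
    "CVResult",
    "LRTResult",
    "back_transform",
    "cross_validate",
    "likelihood_ratio_test",
    "metric_power_correlations",
]

EVENT_METRICS = frozenset(
    {"n_events", "last_duration_s", "last_amplitude", "last_timing_s"})


def back_transform(estimate: float) -> float:
    """Percent change in raw MEP amplitude per unit increase of the metric:
    (e^b - 1) * 100, for an estimate b on the natural-log scale."""
    return float((np.exp(estimate) - 1.0) * 100.0)


class MEPModel:
    """Linear mixed model: log MEP ~ metrics, random intercept per subject.

    Parameters
    ----------
    table : DataFrame
        Per-trial metric table.  Must contain ``subject``, ``log_mep`` and
        every requested metric column; rows with ``excluded == True`` or
        missing values in the used columns are dropped.
    metrics : str or sequence of str
        Fixed-effect metric name(s).
    event_trials_only : bool, optional
        Restrict to trials with ``event_present == 1``.  Defaults to True
        when any requested metric is event-conditional, else False.
    """

    def __init__(self, table: pd.DataFrame, metrics,
                 event_trials_only: bool | None = None):
        if isinstance(metrics, str):
            metrics = [metrics]
        self.metrics = list(metrics)
        if not self.metrics:
            raise ValueError("at least one fixed-effect metric is required")
        if event_trials_only is None:
            event_trials_only = bool(set(self.metrics) & EVENT_METRICS)
        self.event_trials_only = bool(event_trials_only)

        df = table.copy()
        if "excluded" in df.columns:
            df = df[~df["excluded"].astype(bool)]
        if self.event_trials_only:
            df = df[df["event_present"] == 1]
        cols = ["subject", "log_mep", *self.metrics]
        if "trial" in df.columns:
            cols.append("trial")
        df = df[cols].dropna(subset=["log_mep", *self.metrics])
        if df["subject"].nunique() < 2:
            raise ValueError("mixed model requires >= 2 subjects")
        for m in self.metrics:
            if np.asarray(df[m], dtype=float).std() == 0:
                raise ValueError(f"predictor {m!r} has zero variance")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_metrics(cls, table: pd.DataFrame, metric: str,
                     **kwargs) -> "MEPModel":
        return cls(table, metric, **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self) -> "MEPResults":
        """Maximum-likelihood fit; a singular random-effects fit falls back
        to pooled OLS with a warning (flagged on the results)."""
        endog = self.data["log_mep"].to_numpy(dtype=float)
        exog = sm.add_constant(
            self.data[self.metrics].to_numpy(dtype=float), has_constant="add")
        names = ["Intercept", *self.metrics]
        groups = self.data["subject"].to_numpy()

        mixed = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                mixed = sm.MixedLM(endog, exog, groups=groups).fit(reml=False)
            except (np.linalg.LinAlgError, ValueError):
                mixed = None

        singular = (
            mixed is None
            or not np.all(np.isfinite(mixed.fe_params))
            or float(np.asarray(mixed.cov_re)[0, 0]) < 1e-10 * endog.var()
        )
        if singular:
            warnings.warn(
                "singular random-effects fit; falling back to pooled OLS",
                stacklevel=2)
            ols = sm.OLS(endog, exog).fit()
            params = pd.Series(ols.params, index=names)
            ci = pd.DataFrame(ols.conf_int(), index=names,
                              columns=["ci_low", "ci_high"])
            pvalues = pd.Series(ols.pvalues, index=names)
            k = len(names) + 1  # + residual variance
            return MEPResults(
                model=self, params=params, conf_int_=ci, pvalues=pvalues,
                llf=float(ols.llf), aic=float(-2 * ols.llf + 2 * k),
                nobs=int(ols.nobs), random_effects={},
                fallback_ols=True, _fit=ols)

        params = pd.Series(mixed.fe_params, index=names)
        re = {g: float(v.iloc[0]) for g, v in mixed.random_effects.items()}
        if float(mixed.scale) < 1e-10 * endog.var():
            # residual variance at the zero boundary (deterministic data):
            # the ML solution tends to the exact within-subject estimator,
            # which the iterative optimizer only approaches to its tolerance
            params, re = _within_refinement(
                endog, exog[:, 1:], groups, names)
        ci_all = mixed.conf_int()
        ci = pd.DataFrame(np.asarray(ci_all)[:len(names)], index=names,
                          columns=["ci_low", "ci_high"])
        pvalues = pd.Series(np.asarray(mixed.pvalues)[:len(names)],
                            index=names)
        k = len(names) + 2  # + random-intercept variance + residual variance
        return MEPResults(
            model=self, params=params, conf_int_=ci, pvalues=pvalues,
            llf=float(mixed.llf), aic=float(-2 * mixed.llf + 2 * k),
            nobs=int(mixed.nobs), random_effects=re,
            fallback_ols=False, _fit=mixed)


def _within_refinement(endog, x, groups, names):
    """Exact sigma2_eps -> 0 limit of the random-intercept ML fit: slopes
    from within-subject demeaned OLS, intercepts from the group means."""
    gm_y = pd.Series(endog).groupby(pd.Series(groups)).transform("mean")
    xw = x - pd.DataFrame(x).groupby(pd.Series(groups)).transform("mean")
    beta, *_ = np.linalg.lstsq(xw.to_numpy(), endog - gm_y.to_numpy(),
                               rcond=None)
    resid = endog - x @ beta
    group_means = pd.Series(resid).groupby(pd.Series(groups)).mean()
    intercept = float(group_means.mean())
    params = pd.Series([intercept, *beta], index=names)
    re = (group_means - intercept).to_dict()
    return params, re


@dataclass
class MEPResults:
    """Fitted metric -> MEP model: estimates, uncertainty and diagnostics."""

    model: MEPModel
    params: pd.Series
    conf_int_: pd.DataFrame
    pvalues: pd.Series
    llf: float
    aic: float
    nobs: int
    random_effects: dict
    fallback_ols: bool
    _fit: object = field(repr=False, default=None)

    def conf_int(self) -> pd.DataFrame:
        return self.conf_int_.copy()

    @property
    def percent_change(self) -> pd.DataFrame:
        """(e^b - 1) * 100 for every metric estimate and its CI bounds."""
        rows = {}
        for m in self.model.metrics:
            rows[m] = {
                "percent": back_transform(self.params[m]),
                "ci_low": back_transform(self.conf_int_.loc[m, "ci_low"]),
                "ci_high": back_transform(self.conf_int_.loc[m, "ci_high"]),
            }
        return pd.DataFrame(rows).T

    def predict(self, table: pd.DataFrame,
                include_random_intercept: bool = True) -> np.ndarray:
        """Predicted log MEP for new trials: fixed effects plus (optionally)
        each trial's subject random intercept (0 for unseen subjects)."""
        pred = np.full(len(table), self.params["Intercept"], dtype=float)
        for m in self.model.metrics:
            pred += self.params[m] * table[m].to_numpy(dtype=float)
        if include_random_intercept:
            pred += table["subject"].map(
                lambda s: self.random_effects.get(s, 0.0)).to_numpy()
        return pred

    def cross_validate(self, k: int = 10, seed: int = 0,
                       include_random_intercept: bool = True) -> "CVResult":
        return cross_validate(
            self.model.data, self.model.metrics, k=k, seed=seed,
            event_trials_only=False,  # model data is already filtered
            include_random_intercept=include_random_intercept)

    def summary(self) -> str:
        lines = [
            "Mixed-effects model of log MEP amplitude"
            + ("  [pooled-OLS fallback]" if self.fallback_ols else ""),
            f"  fixed effects: {', '.join(self.model.metrics)}"
            + "    random intercept: subject",
            f"  N trials = {self.nobs}   "
            f"subjects = {self.model.data['subject'].nunique()}   "
            f"trials filter = "
            f"{'event trials' if self.model.event_trials_only else 'all'}",
            f"  log-likelihood = {self.llf:.1f}   AIC = {self.aic:.1f}",
            "",
            f"  {'term':<16}{'estimate':>10}{'95% CI':>22}"
            f"{'p':>12}{'% change':>10}",
        ]
        for name in self.params.index:
            lo, hi = self.conf_int_.loc[name]
            pct = (f"{back_transform(self.params[name]):10.2f}"
                   if name != "Intercept" else " " * 10)
            lines.append(
                f"  {name:<16}{self.params[name]:10.4f}"
                f"   [{lo:8.4f} {hi:8.4f}]{self.pvalues[name]:12.2e}{pct}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    folds: pd.DataFrame          # fold, rho, p, rmse, n_test
    mean_rho: float
    mean_rmse: float
    nrmse: float                 # mean RMSE / range of observed log MEP
    k: int
    seed: int
    assignment: pd.Series        # fold index per trial (index = row order)


def _fold_assignment(subjects: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Per-subject stratified fold labels by seeded shuffle (balanced)."""
    rng = np.random.default_rng(seed)
    fold = np.empty(subjects.size, dtype=int)
    for subj in pd.unique(subjects):
        rows = np.flatnonzero(subjects == subj)
        if rows.size < k:
            raise ValueError(
                f"subject {subj} has {rows.size} trials, fewer than k={k}")
        order = rng.permutation(rows)
        fold[order] = np.arange(rows.size) % k
    return fold


def cross_validate(table: pd.DataFrame, metrics, k: int = 10, seed: int = 0,
                   event_trials_only: bool | None = None,
                   include_random_intercept: bool = True) -> CVResult:
    """k-fold cross-validation with per-subject 90/10 splits.

    Each fold refits the mixed model on the training trials and predicts the
    held-out trials (fixed effects + the subject's fitted random intercept);
    Spearman's rho and the RMSE between predicted and actual log MEP are
    averaged over folds, and the mean RMSE is normalized by the range of the
    observed log MEP amplitudes.
    """
    model = MEPModel(table, metrics, event_trials_only=event_trials_only)
    data = model.data
    fold = _fold_assignment(data["subject"].to_numpy(), k, seed)

    rows = []
    for f in range(k):
        test = data[fold == f]
        train = data[fold != f]
        res = MEPModel(train, model.metrics,
                       event_trials_only=False).fit()
        pred = res.predict(test, include_random_intercept)
        actual = test["log_mep"].to_numpy(dtype=float)
        rho, p = sps.spearmanr(pred, actual)
        rmse = float(np.sqrt(np.mean((pred - actual) ** 2)))
        rows.append({"fold": f, "rho": float(rho), "p": float(p),
                     "rmse": rmse, "n_test": len(test)})
    folds = pd.DataFrame(rows)
    obs = data["log_mep"].to_numpy(dtype=float)
    rng_obs = float(obs.max() - obs.min())
    mean_rmse = float(folds["rmse"].mean())
    return CVResult(
        folds=folds,
        mean_rho=float(folds["rho"].mean()),
        mean_rmse=mean_rmse,
        nrmse=mean_rmse / rng_obs,
        k=k, seed=seed,
        assignment=pd.Series(fold, index=data.index, name="fold"))


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------

@dataclass
class LRTResult:
    statistic: float
    df: int
    pvalue: float


def likelihood_ratio_test(simple: MEPResults,
                          complex: MEPResults) -> LRTResult:
    """Likelihood-ratio test between nested maximum-likelihood fits:
    2*(ll_complex - ll_simple) ~ chi2 with df = parameter difference."""
    s_terms, c_terms = set(simple.model.metrics), set(complex.model.metrics)
    if not s_terms <= c_terms:
        raise ValueError("models are not nested")
    if simple.nobs != complex.nobs:
        raise ValueError("models were fit on different trial sets")
    if "trial" in simple.model.data and "trial" in complex.model.data:
        if not np.array_equal(np.sort(simple.model.data["trial"]),
                              np.sort(complex.model.data["trial"])):
            raise ValueError("models were fit on different trial sets")
    df = len(c_terms) - len(s_terms)
    stat = max(2.0 * (complex.llf - simple.llf), 0.0)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTResult(statistic=float(stat), df=df, pvalue=p)


# --------------------------------------------------------------------------
# collinearity of event metrics with mean power
# --------------------------------------------------------------------------

def metric_power_correlations(
    table: pd.DataFrame,
    metrics=("n_events", "last_duration_s", "last_amplitude"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject Spearman correlation of each event metric with mean beta
    power, plus the group mean +/- SEM.  Subjects with a constant metric are
    excluded from that metric's mean with a warning."""
    df = table
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    per_rows = []
    for subj, g in df.groupby("subject"):
        if len(g) < 3:
            raise ValueError(f"subject {subj} has < 3 trials")
        row = {"subject": subj}
        for m in metrics:
            sub = g.dropna(subset=[m, "mean_power"])
            if len(sub) < 3 or sub[m].std() == 0 or sub["mean_power"].std() == 0:
                warnings.warn(
                    f"constant {m} for subject {subj}: rho undefined",
                    stacklevel=2)
                row[m] = np.nan
                continue
            row[m] = float(sps.spearmanr(sub[m], sub["mean_power"])[0])
        per_rows.append(row)
    per_subject = pd.DataFrame(per_rows)
    summary = pd.DataFrame({
        "mean_rho": per_subject[list(metrics)].mean(),
        "sem": per_subject[list(metrics)].sem(),
        "n_subjects": per_subject[list(metrics)].notna().sum(),
    })
    return per_subject, summary
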