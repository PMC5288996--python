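"""Proportional-hazards survival modelling and prediction-performance metrics.

Cox models (Efron tie handling) relate the mdNLR — continuous, or
dichotomized at the clinical cut point — and single-CpG predictors to
overall survival, adjusted for age, sex, tumour grade and mutation
subtype.  Model comparison uses Harrell's concordance index, the
inverse-probability-of-censoring-weighted (IPCW) Brier score, the
cumulative/dynamic IPCW time-dependent AUROC, and partial-likelihood
ratio tests against a named baseline model.  Proportionality is checked
with the Grambsch-Therneau test on scaled Schoenfeld residuals.

Cox fitting, Kaplan-Meier estimation and the log-rank test are delegated
to lifelines; the diagnostics and IPCW metrics are computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

MAX_NEWTON_STEPS = 100
SEPARATION_COEF = 20.0


@dataclass
class CoxFitResult:
    """A fitted Cox model: coefficient table, likelihood and bookkeeping.

    ``summary`` is indexed by covariate with columns ``coef``, ``hr``,
    ``hr_lower``, ``hr_upper`` (Wald 95% CI) and ``p``.
    """

    covariates: list[str]
    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    separation_flags: list[str]
    fitter: CoxPHFitter
    duration_col: str
    event_col: str

    def predict_survival(self, records: pd.DataFrame, times) -> pd.DataFrame:
        """Predicted survival probabilities, times x samples."""
        return self.fitter.predict_survival_function(
            records[self.covariates], times=np.asarray(times, dtype=float)
        )

    def risk_score(self, records: pd.DataFrame) -> pd.Series:
        """Linear predictor (log partial hazard); higher = higher risk."""
        return self.fitter.predict_log_partial_hazard(records[self.covariates])


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFitResult:
    """Maximize the Efron-tied partial likelihood for the given covariates.

    Deterministic given the data.  Coefficients with |coef| > 20 are
    flagged as likely separation.
    """
    if not covariates:
        raise ValueError("at least one covariate is required")
    data = records[[duration_col, event_col, *covariates]]
    if data[event_col].sum() < 1:
        raise ValueError("at least one event is required")
    constant = [c for c in covariates if data[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates cannot be fit: {constant}")

    fitter = CoxPHFitter()
    fitter.fit(
        data,
        duration_col=duration_col,
        event_col=event_col,
        fit_options={"max_steps": MAX_NEWTON_STEPS, "precision": 1e-10},
    )
    s = fitter.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    flags = list(summary.index[summary["coef"].abs() > SEPARATION_COEF])
    return CoxFitResult(
        covariates=list(covariates),
        summary=summary,
        log_likelihood=float(fitter.log_likelihood_),
        n=len(data),
        n_events=int(data[event_col].sum()),
        converged=True,
        separation_flags=flags,
        fitter=fitter,
        duration_col=duration_col,
        event_col=event_col,
    )


# ---------------------------------------------------------------------------
# Proportionality (Grambsch-Therneau on scaled Schoenfeld residuals)
# ---------------------------------------------------------------------------


def test_proportionality(fit: CoxFitResult, records: pd.DataFrame) -> pd.DataFrame:
    """Test a zero slope of scaled Schoenfeld residuals against time.

    Uses the identity time transform.  Returns one row per covariate with
    the Pearson correlation of the scaled residuals with event time, the
    Grambsch-Therneau chi-square statistic and its p-value, plus a
    ``GLOBAL`` row (df = number of covariates); for a single-covariate
    model the global test coincides with the per-covariate test.
    """
    data = records[[fit.duration_col, fit.event_col, *fit.covariates]]
    if data[fit.event_col].sum() < 3:
        raise ValueError("need >= 3 events to assess proportionality")
    resid = fit.fitter.compute_residuals(data, kind="schoenfeld")
    times = data.loc[resid.index, fit.duration_col]
    resid = resid.loc[times.sort_values().index]
    s = resid[fit.covariates].to_numpy()  # d x p, one row per event
    g = times.sort_values().to_numpy(dtype=float)  # identity transform
    d = s.shape[0]
    v = fit.fitter.variance_matrix_.loc[fit.covariates, fit.covariates].to_numpy()

    gc = g - g.mean()
    ssg = float((gc**2).sum())
    scaled = d * (s @ v)  # scaled Schoenfeld residuals (up to the +beta shift)
    x = scaled.T @ gc  # p-vector

    rows = []
    for j, cov in enumerate(fit.covariates):
        stat = x[j] ** 2 / (d * v[j, j] * ssg)
        corr = float(np.corrcoef(scaled[:, j], g)[0, 1])
        rows.append(
            {
                "covariate": cov,
                "corr_with_time": corr,
                "chi2": stat,
                "df": 1,
                "p": float(stats.chi2.sf(stat, 1)),
            }
        )
    global_stat = float(x @ np.linalg.solve(v, x) / (d * ssg))
    p_dim = len(fit.covariates)
    rows.append(
        {
            "covariate": "GLOBAL",
            "corr_with_time": float("nan"),
            "chi2": global_stat,
            "df": p_dim,
            "p": float(stats.chi2.sf(global_stat, p_dim)),
        }
    )
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def concordance_index(
    scores, time, event
) -> tuple[float, float, int]:
    """Harrell's c over comparable pairs, with a pair-based SE.

    A pair is comparable when the earlier time is an observed event and
    the times differ.  Tied risk scores count 0.5.  Returns
    ``(c, se, n_pairs)``; c is NaN when no pair is comparable.  SE is the
    standard ``sqrt(c(1-c)/n_pairs)`` pair-based estimator.
    """
    r = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    # i earlier than j, i an event -> comparable; higher risk should fail first
    earlier = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    conc = float((earlier & (r[:, None] > r[None, :])).sum())
    ties = float((earlier & (r[:, None] == r[None, :])).sum())
    n_pairs = int(earlier.sum())
    if n_pairs == 0:
        return float("nan"), float("nan"), 0
    c = (conc + 0.5 * ties) / n_pairs
    se = float(np.sqrt(c * (1.0 - c) / n_pairs))
    return c, se, n_pairs


def concordance_from_fit(fit: CoxFitResult, records: pd.DataFrame):
    """Convenience wrapper: c-index of a fitted model's risk score."""
    return concordance_index(
        fit.risk_score(records), records[fit.duration_col], records[fit.event_col]
    )


# ---------------------------------------------------------------------------
# IPCW censoring weights
# ---------------------------------------------------------------------------


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimate of the censoring survival G(t).

    Returns ``(G, G_minus)`` callables evaluating G right-continuously and
    at the left limit t-.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)

    def g(t):
        idx = np.searchsorted(grid, np.asarray(t, dtype=float), side="right") - 1
        return vals[np.clip(idx, 0, len(vals) - 1)]

    def g_minus(t):
        idx = np.searchsorted(grid, np.asarray(t, dtype=float), side="left") - 1
        return vals[np.clip(idx, 0, len(vals) - 1)]

    return g, g_minus


# ---------------------------------------------------------------------------
# Brier score
# ---------------------------------------------------------------------------


def brier_score(
    surv_prob: pd.DataFrame,
    records: pd.DataFrame,
    eval_times,
    duration_col: str = "time",
    event_col: str = "event",
) -> tuple[pd.Series, float]:
    """IPCW prediction error with Kaplan-Meier censoring weights.

    ``surv_prob`` holds predicted survival probabilities, times x samples
    (aligned with ``records``).  At each evaluation time t the squared
    error of the survival prediction is weighted by 1/G(T-) for events
    before t and 1/G(t) for samples still at risk; times where the
    censoring survival vanishes are dropped with a warning.  Returns the
    per-time scores and the trapezoid-integrated Brier score over the
    retained grid.
    """
    t_obs = records[duration_col].to_numpy(dtype=float)
    e_obs = records[event_col].to_numpy(dtype=int)
    eval_times = np.asarray(eval_times, dtype=float)
    g, g_minus = _censoring_km(t_obs, e_obs)

    scores = {}
    for t in eval_times:
        gt = g(t)
        s_hat = surv_prob.loc[t].to_numpy(dtype=float)
        died = (t_obs <= t) & (e_obs == 1)
        at_risk = t_obs > t
        w_died = np.zeros_like(t_obs)
        g_tm = g_minus(t_obs[died])
        if np.any(g_tm <= 0) or gt <= 0:
            warnings.warn(
                f"censoring weight vanished at t={t:g}; time dropped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        w_died[died] = 1.0 / g_tm
        contrib = (0.0 - s_hat) ** 2 * w_died + (1.0 - s_hat) ** 2 * at_risk / gt
        scores[t] = float(contrib.mean())

    series = pd.Series(scores, name="brier")
    if len(series) >= 2:
        span = series.index[-1] - series.index[0]
        integrated = float(np.trapezoid(series.to_numpy(), series.index.to_numpy()) / span)
    elif len(series) == 1:
        integrated = float(series.iloc[0])
    else:
        integrated = float("nan")
    return series, integrated


# ---------------------------------------------------------------------------
# Time-dependent AUROC
# ---------------------------------------------------------------------------


def time_dependent_auroc(
    scores,
    records: pd.DataFrame,
    eval_times,
    duration_col: str = "time",
    event_col: str = "event",
) -> tuple[pd.Series, float]:
    """Cumulative-case / dynamic-control AUROC with IPCW weights.

    At each t, cases are subjects with an observed event by t (weight
    1/G(T-)) and controls are subjects still at risk after t (weight
    1/G(t)); the AUROC is the weighted probability that a case outranks a
    control, ties counting half.  Times with no cases or no controls are
    skipped.  The summary is the unweighted mean over the evaluated grid.
    """
    r = np.asarray(scores, dtype=float)
    t_obs = records[duration_col].to_numpy(dtype=float)
    e_obs = records[event_col].to_numpy(dtype=int)
    eval_times = np.asarray(eval_times, dtype=float)
    g, g_minus = _censoring_km(t_obs, e_obs)

    aucs = {}
    for t in eval_times:
        cases = (t_obs <= t) & (e_obs == 1)
        controls = t_obs > t
        if not cases.any() or not controls.any():
            continue
        gt = g(t)
        g_tm = g_minus(t_obs[cases])
        if gt <= 0 or np.any(g_tm <= 0):
            continue
        w_case = 1.0 / g_tm
        w_ctrl = np.full(int(controls.sum()), 1.0 / gt)
        rc, rk = r[cases], r[controls]
        greater = (rc[:, None] > rk[None, :]).astype(float)
        tied = (rc[:, None] == rk[None, :]).astype(float)
        w = w_case[:, None] * w_ctrl[None, :]
        aucs[t] = float((w * (greater + 0.5 * tied)).sum() / w.sum())

    series = pd.Series(aucs, name="auroc")
    summary = float(series.mean()) if len(series) else float("nan")
    return series, summary


# ---------------------------------------------------------------------------
# Likelihood-ratio test and Kaplan-Meier
# ---------------------------------------------------------------------------


def likelihood_ratio_test(
    fit_full: CoxFitResult, fit_nested: CoxFitResult
) -> tuple[float, int, float]:
    """Partial-likelihood ratio test of nested Cox models.

    Returns ``(statistic, df, p)`` where the statistic is twice the
    log-likelihood difference and df the parameter-count difference.
    """
    if not set(fit_nested.covariates) <= set(fit_full.covariates):
        raise ValueError("models are not nested")
    if (fit_full.n, fit_full.n_events) != (fit_nested.n, fit_nested.n_events):
        raise ValueError("models must be fit on the same records")
    df = len(fit_full.covariates) - len(fit_nested.covariates)
    stat = max(2.0 * (fit_full.log_likelihood - fit_nested.log_likelihood), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def kaplan_meier(
    records: pd.DataFrame,
    group_by: str | None = None,
    duration_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Product-limit curves per group, medians and the log-rank test.

    The median is the earliest time with S(t) <= 0.5 (NaN when never
    reached).  With two or more groups a standard log-rank test is
    reported.
    """
    if group_by is None:
        groups = pd.Series("all", index=records.index)
    else:
        groups = records[group_by]
    curves, medians = {}, {}
    for label in pd.unique(groups):
        sub = records[groups == label]
        if len(sub) < 1:
            raise ValueError(f"group {label} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col], label=str(label))
        curves[label] = kmf.survival_function_.iloc[:, 0]
        medians[label] = float(kmf.median_survival_time_)
    out = {"curves": curves, "median": medians}
    if groups.nunique() >= 2:
        lr = multivariate_logrank_test(
            records[duration_col], groups, records[event_col]
        )
        out["logrank_stat"] = float(lr.test_statistic)
        out["logrank_p"] = float(lr.p_value)
    return out
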