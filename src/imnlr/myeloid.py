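"""Myeloid-lineage CpG discovery and single-locus mdNLR surrogates.

The mdNLR needs a few hundred L-DMRs and a deconvolution step; a single
CpG that demethylates during myeloid differentiation can stand in for it.
The screen has three stages: (i) per-CpG linear models of purified-cell
M-values on a myeloid-vs-lymphoid indicator, adjusting for the measured
blood cell proportions of the source samples; (ii) a deterministic top-k
cut on the |t|-ranked table; (iii) polynomial regressions (degree 1-3) of
the mdNLR on each candidate locus's M-values, keeping loci whose
best-degree adjusted R^2 clears a threshold in every evaluated dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import BetaMatrix

MYELOID_TYPES = ("Mono", "Gran")
DEFAULT_TOP_K = 100
DEFAULT_ADJ_R2_THRESHOLD = 0.80
DEFAULT_DEGREES = (1, 2, 3)
_CONDITION_WARN = 1e8


# ---------------------------------------------------------------------------
# Lineage model
# ---------------------------------------------------------------------------


def fit_lineage_model(
    purified_m: pd.DataFrame,
    lineage_labels: pd.Series,
    measured_props: pd.DataFrame,
) -> pd.DataFrame:
    """Per-CpG OLS of M-values on lineage, adjusted for blood composition.

    ``purified_m`` is CpG x sample; ``lineage_labels`` maps each sample to
    ``myeloid`` or ``lymphoid``; ``measured_props`` holds each sample's
    measured blood cell fractions (one column is dropped — the last in the
    fixed cell-type order — to break the sum-to-one collinearity).

    Returns a table indexed by CpG with ``lineage_coef`` (adjusted myeloid
    minus lymphoid M difference), ``t_stat`` and ``rank`` (1 = largest
    |t|; ties broken by CpG id).
    """
    samples = purified_m.columns
    labels = lineage_labels.reindex(samples)
    if labels.isna().any():
        raise ValueError("lineage_labels must cover every sample")
    bad = set(labels.unique()) - {"myeloid", "lymphoid"}
    if bad:
        raise ValueError(f"unknown lineage labels: {sorted(bad)}")
    if (labels == "myeloid").sum() < 3 or (labels == "lymphoid").sum() < 3:
        raise ValueError("need >= 3 samples per lineage")
    props = measured_props.reindex(samples)
    if props.isna().any().any():
        raise ValueError("measured_props must align with the M-value samples")

    indicator = (labels == "myeloid").astype(float).to_numpy()
    covars = props.iloc[:, :-1]  # drop last column (sum-to-one)
    covars = covars.loc[:, covars.nunique() > 1]  # constants join the intercept
    z = np.column_stack([np.ones(len(samples)), indicator, covars.to_numpy()])
    rank = np.linalg.matrix_rank(z)
    if rank < z.shape[1]:
        raise ValueError(
            "collinear covariates after dropping the last proportion column: "
            f"{list(covars.columns)}"
        )

    y = purified_m.to_numpy().T  # samples x cpgs
    ztz_inv = np.linalg.inv(z.T @ z)
    coefs = ztz_inv @ (z.T @ y)  # p x cpgs
    resid = y - z @ coefs
    dof = z.shape[0] - z.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * ztz_inv[1, 1], 1e-300))
    t = coefs[1] / se

    table = pd.DataFrame(
        {"lineage_coef": coefs[1], "t_stat": t}, index=purified_m.index
    )
    order = np.lexsort((table.index.to_numpy(), -np.abs(t)))
    ranks = np.empty(len(t), dtype=int)
    ranks[order] = np.arange(1, len(t) + 1)
    table["rank"] = ranks
    return table


def select_top_loci(stats_table: pd.DataFrame, k: int = DEFAULT_TOP_K) -> list[str]:
    """Deterministic top-k CpGs by |t| (descending), ties by id."""
    if k > len(stats_table):
        raise ValueError("k exceeds the number of scored CpGs")
    ordered = stats_table.sort_values("rank")
    return list(ordered.index[:k])


# ---------------------------------------------------------------------------
# Polynomial surrogate fits
# ---------------------------------------------------------------------------


@dataclass
class SurrogateLocusResult:
    """Polynomial fits of the mdNLR on one locus's M-values."""

    cpg_id: str
    adj_r2: dict[int, float] = field(default_factory=dict)
    coefficients: dict[int, np.ndarray] = field(default_factory=dict)
    best_degree: int | None = None
    best_adj_r2: float = float("nan")
    reason: str | None = None  # set when the fit is undefined

    @property
    def defined(self) -> bool:
        return self.reason is None


def _adjusted_r2(y: np.ndarray, fitted: np.ndarray, n_params: int) -> float:
    n = len(y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - float(((y - fitted) ** 2).sum()) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def fit_mdnlr_surrogate(
    mdnlr: pd.Series,
    locus_m: pd.Series,
    degrees: Sequence[int] = DEFAULT_DEGREES,
    cpg_id: str | None = None,
) -> SurrogateLocusResult:
    """Least-squares polynomials of the mdNLR on one locus's M-values.

    For each degree d the adjusted R^2 is ``1 - (1 - R^2)(n-1)/(n-d-1)``;
    the best degree maximizes it.  Raw (non-orthogonalized) powers of M are
    used; a conditioning warning is emitted when the Vandermonde design's
    condition number exceeds 1e8.  A constant locus leaves the fit
    undefined (``reason`` set, never selected).
    """
    degrees = sorted(set(int(d) for d in degrees))
    if not degrees or set(degrees) - {1, 2, 3}:
        raise ValueError("degrees must be a nonempty subset of {1, 2, 3}")
    x = locus_m.reindex(mdnlr.index)
    if x.isna().any() or mdnlr.isna().any():
        raise ValueError("mdnlr and locus M-values must align and be finite")
    xv, yv = x.to_numpy(dtype=float), mdnlr.to_numpy(dtype=float)
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("inputs must be finite")
    name = cpg_id if cpg_id is not None else str(locus_m.name)
    result = SurrogateLocusResult(cpg_id=name)
    if np.ptp(xv) == 0:
        result.reason = "constant locus M-values: R^2 undefined"
        return result
    if len(yv) < max(degrees) + 2:
        raise ValueError("need at least degree + 2 samples")

    for d in degrees:
        design = np.vander(xv, d + 1)
        cond = np.linalg.cond(design)
        if cond > _CONDITION_WARN:
            warnings.warn(
                f"ill-conditioned degree-{d} polynomial design for {name} "
                f"(condition number {cond:.2e})",
                RuntimeWarning,
                stacklevel=2,
            )
        coefs = np.polyfit(xv, yv, d)
        result.coefficients[d] = coefs
        result.adj_r2[d] = _adjusted_r2(yv, np.polyval(coefs, xv), d)

    best = max(result.adj_r2, key=lambda d: (result.adj_r2[d], -d))
    result.best_degree = best
    result.best_adj_r2 = result.adj_r2[best]
    return result


def screen_surrogates(
    mdnlr: pd.Series,
    m_values: pd.DataFrame,
    loci: Sequence[str],
    degrees: Sequence[int] = DEFAULT_DEGREES,
) -> pd.DataFrame:
    """Fit every candidate locus and tabulate adjusted R^2 per degree."""
    rows = {}
    for cpg in loci:
        res = fit_mdnlr_surrogate(mdnlr, m_values.loc[cpg], degrees, cpg_id=cpg)
        row = {f"adj_r2_deg{d}": res.adj_r2.get(d, float("nan")) for d in degrees}
        row["best_degree"] = res.best_degree
        row["best_adj_r2"] = res.best_adj_r2
        row["reason"] = res.reason
        rows[cpg] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cpg_id"
    return out


def select_consistent_surrogates(
    results_per_dataset: Sequence[pd.DataFrame],
    threshold: float = DEFAULT_ADJ_R2_THRESHOLD,
) -> list[str]:
    """Loci whose best adjusted R^2 clears the threshold in every dataset.

    Loci absent from any dataset (or with undefined fits) are excluded.
    The result is sorted by mean adjusted R^2, descending (ties by id).
    """
    if not results_per_dataset:
        raise ValueError("at least one dataset of results is required")
    common: pd.Index | None = None
    for res in results_per_dataset:
        defined = res.index[res["reason"].isna()] if "reason" in res else res.index
        common = defined if common is None else common.intersection(defined)
    scores = pd.DataFrame(
        {i: res["best_adj_r2"].reindex(common) for i, res in enumerate(results_per_dataset)}
    )
    passing = scores.index[(scores >= threshold).all(axis=1)]
    mean_r2 = scores.loc[passing].mean(axis=1)
    order = sorted(passing, key=lambda c: (-mean_r2[c], c))
    return list(order)


# ---------------------------------------------------------------------------
# Group comparisons (percentage-scale medians + Mann-Whitney U)
# ---------------------------------------------------------------------------


def compare_groups_by_locus(
    beta: BetaMatrix | pd.DataFrame,
    groups: pd.Series,
    loci: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-CpG median (IQR) beta on the percentage scale, by group, with a
    two-sided Mann-Whitney U test (exact when both groups have <= 20
    samples, normal approximation otherwise)."""
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        raise ValueError("groups must cover every sample")
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    n_a = int((groups == levels[0]).sum())
    n_b = int((groups == levels[1]).sum())
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    method = "exact" if max(n_a, n_b) <= 20 else "asymptotic"

    sub = values.loc[loci] if loci is not None else values
    a = sub.loc[:, (groups == levels[0]).to_numpy()].to_numpy() * 100.0
    b = sub.loc[:, (groups == levels[1]).to_numpy()].to_numpy() * 100.0

    rows = []
    for i, cpg in enumerate(sub.index):
        u, p = stats.mannwhitneyu(a[i], b[i], alternative="two-sided", method=method)
        qa = np.percentile(a[i], [25, 50, 75])
        qb = np.percentile(b[i], [25, 50, 75])
        rows.append(
            {
                "cpg_id": cpg,
                f"median_{levels[0]}": qa[1],
                f"iqr_low_{levels[0]}": qa[0],
                f"iqr_high_{levels[0]}": qa[2],
                f"median_{levels[1]}": qb[1],
                f"iqr_low_{levels[1]}": qb[0],
                f"iqr_high_{levels[1]}": qb[2],
                "u_stat": u,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("cpg_id")
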