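"""Reference-based leukocyte deconvolution and the mdNLR score.

Whole-blood methylation is modelled as a convex combination of purified
cell-type profiles.  Leukocyte-discriminating CpGs (L-DMRs) are selected
from a purified reference panel by one-vs-rest t-statistics on M-values;
mixture proportions are then estimated per sample by constrained
projection — least squares subject to nonnegativity and a unit-sum bound —
and summarized as the methylation-derived neutrophil-to-lymphocyte ratio

    mdNLR_i = omega_hat(Gran, i) / omega_hat(Lymph, i),

the estimated granulocyte fraction over the summed CD4T+CD8T+B+NK
fractions (monocytes enter neither term).  Scores are dichotomized at a
configurable cut point (4.0 by convention, boundary assigned high).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .preprocessing import BetaMatrix, beta_to_m

CELL_TYPES = ("CD4T", "CD8T", "B", "NK", "Mono", "Gran")
LYMPHOID_TYPES = CELL_TYPES[:4]

#: Convergence tolerance of the constrained projection.
SOLVER_TOL = 1e-9

#: Default lymphocyte floor guaranteeing a finite mdNLR.
DEFAULT_LYMPH_FLOOR = 1e-4

#: Default mdNLR cut point (elevated-NLR convention from the clinical NLR
#: literature).
DEFAULT_CUTPOINT = 4.0

#: Minimum fraction of library CpGs that must be present in a target matrix.
MIN_LIBRARY_OVERLAP = 0.5


@dataclass
class ReferenceLibrary:
    """Selected L-DMRs with mean beta per purified cell type.

    ``design`` is the CpG x cell-type mixture design matrix.
    """

    design: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.design
        if d.index.has_duplicates:
            raise ValueError("reference library contains duplicate CpGs")
        arr = d.to_numpy()
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("design matrix values must lie in [0, 1]")
        # Degenerate libraries (two identical cell-type columns) cannot be
        # deconvolved.
        cols = arr.T
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if np.abs(cols[i] - cols[j]).mean() == 0:
                    raise ValueError(
                        f"cell types {d.columns[i]} and {d.columns[j]} have "
                        "identical profiles"
                    )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.design.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.design.columns)


@dataclass
class CellProportionTable:
    """Estimated cell fractions with per-sample residual norms."""

    omega: pd.DataFrame  # sample x cell type, nonnegative
    residual_norm: pd.Series

    @property
    def sample_ids(self) -> pd.Index:
        return self.omega.index

    def normalized(self) -> "CellProportionTable":
        """Rows rescaled to the unit simplex (rows with zero sum unchanged)."""
        sums = self.omega.sum(axis=1)
        scale = sums.where(sums > 0, 1.0)
        return CellProportionTable(
            omega=self.omega.div(scale, axis=0), residual_norm=self.residual_norm
        )


@dataclass
class MdnlrScore:
    """Per-sample mdNLR with floor flags and optional group labels."""

    mdnlr: pd.Series
    floored: pd.Series
    group: pd.Series | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.mdnlr.index


# ---------------------------------------------------------------------------
# Library selection
# ---------------------------------------------------------------------------


def select_reference_library(
    purified: BetaMatrix,
    cell_labels: pd.Series,
    n_per_type: int = 50,
) -> ReferenceLibrary:
    """Select L-DMRs by one-vs-rest moderated contrast and build the design.

    For each cell type the CpGs are ranked by the magnitude of the Welch
    two-sample t-statistic (that type's purified samples vs all others) on
    M-values; ``n_per_type`` winners are taken, split evenly between
    hypermethylated (positive t) and hypomethylated (negative t) CpGs when
    both directions are available.  The design matrix holds per-type mean
    beta over the purified samples at the union of selected CpGs.
    """
    labels = cell_labels.reindex(purified.sample_ids)
    if labels.isna().any():
        raise ValueError("cell_labels must cover every purified sample")
    counts = labels.value_counts()
    short = counts[counts < 2]
    if len(short):
        raise ValueError(f"need >= 2 purified samples per type; short: {list(short.index)}")
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    if n_per_type > purified.n_cpgs:
        raise ValueError("n_per_type exceeds the number of available CpGs")

    m_vals = beta_to_m(purified.values).to_numpy()  # cpg x sample
    selected: set[str] = set()
    cpg_ids = purified.cpg_ids.to_numpy()
    for cell in pd.unique(labels):
        mask = (labels == cell).to_numpy()
        a, b = m_vals[:, mask], m_vals[:, ~mask]
        na, nb = a.shape[1], b.shape[1]
        va = a.var(axis=1, ddof=1) / na
        vb = b.var(axis=1, ddof=1) / nb
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(np.maximum(va + vb, 1e-30))
        order = np.lexsort((cpg_ids, -np.abs(t)))  # |t| desc, id asc on ties
        hyper = [i for i in order if t[i] > 0]
        hypo = [i for i in order if t[i] <= 0]
        n_hyper = min(n_per_type // 2, len(hyper))
        n_hypo = min(n_per_type - n_hyper, len(hypo))
        n_hyper = min(n_per_type - n_hypo, len(hyper))  # backfill if one side short
        picked = hyper[:n_hyper] + hypo[:n_hypo]
        selected.update(cpg_ids[picked])

    chosen = sorted(selected)
    beta_sel = purified.values.loc[chosen]
    design = pd.DataFrame(
        {cell: beta_sel.loc[:, (labels == cell).to_numpy()].mean(axis=1)
         for cell in pd.unique(labels)},
    )
    # Fixed cell-type order when the labels match the canonical panel.
    if set(design.columns) == set(CELL_TYPES):
        design = design[list(CELL_TYPES)]
    return ReferenceLibrary(design=design)


# ---------------------------------------------------------------------------
# Constrained projection
# ---------------------------------------------------------------------------


def _solve_projection(xtx: np.ndarray, xty: np.ndarray, yty: float) -> tuple[np.ndarray, float]:
    """argmin ||y - Xw||^2 over {w >= 0, sum(w) <= 1} via SLSQP.

    Works on the quadratic form, so per-sample cost is independent of the
    number of CpGs.  Deterministic start at the centroid of the feasible
    region.
    """
    k = len(xty)

    def objective(w):
        return 0.5 * (w @ xtx @ w) - xty @ w + 0.5 * yty

    def grad(w):
        return xtx @ w - xty

    res = minimize(
        objective,
        x0=np.full(k, 1.0 / (k + 1)),
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                      "jac": lambda w: -np.ones(k)}],
        options={"ftol": SOLVER_TOL * 1e-3, "maxiter": 500},
    )
    w = np.clip(res.x, 0.0, None)
    return w, max(2.0 * objective(w), 0.0)


def estimate_proportions(
    beta: BetaMatrix,
    library: ReferenceLibrary,
    normalize: bool = False,
) -> CellProportionTable:
    """Estimate cell fractions per sample by constrained projection.

    CpGs are aligned by id; at least half of the library CpGs must be
    present in ``beta``.  Each sample's fractions minimize the squared
    residual subject to nonnegativity and a unit-sum bound; with
    ``normalize`` the rows are post-hoc rescaled to the simplex.
    """
    common = library.cpg_ids.intersection(beta.cpg_ids)
    needed = int(np.ceil(MIN_LIBRARY_OVERLAP * len(library.cpg_ids)))
    if len(common) < needed:
        raise ValueError(
            f"only {len(common)} of {len(library.cpg_ids)} library CpGs present "
            f"in the target matrix (need >= {needed})"
        )
    x = library.design.loc[common].to_numpy()
    y = beta.values.loc[common].to_numpy()  # cpg x sample
    xtx = x.T @ x
    xty_all = x.T @ y  # k x samples
    yty_all = (y * y).sum(axis=0)

    k = x.shape[1]
    omega = np.empty((beta.n_samples, k))
    resid = np.empty(beta.n_samples)
    for i in range(beta.n_samples):
        w, sq = _solve_projection(xtx, xty_all[:, i], yty_all[i])
        omega[i] = w
        resid[i] = np.sqrt(sq)

    table = CellProportionTable(
        omega=pd.DataFrame(omega, index=beta.sample_ids, columns=library.cell_types),
        residual_norm=pd.Series(resid, index=beta.sample_ids, name="residual_norm"),
    )
    return table.normalized() if normalize else table


# ---------------------------------------------------------------------------
# mdNLR
# ---------------------------------------------------------------------------


def compute_mdnlr(
    props: CellProportionTable, floor: float = DEFAULT_LYMPH_FLOOR
) -> MdnlrScore:
    """Granulocyte over summed lymphocyte fractions, floored for finiteness.

    ``floor`` bounds the denominator below; samples where the floor was
    binding are flagged.  The ratio is invariant to row rescaling, so raw
    and simplex-normalized fractions give the same score.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    lymph = props.omega[list(LYMPHOID_TYPES)].sum(axis=1)
    floored = lymph < floor
    mdnlr = props.omega["Gran"] / lymph.clip(lower=floor)
    return MdnlrScore(
        mdnlr=mdnlr.rename("mdnlr"), floored=floored.rename("floored")
    )


def dichotomize_mdnlr(
    score: MdnlrScore, cutpoint: float = DEFAULT_CUTPOINT, strict: bool = False
) -> pd.Series:
    """Label samples high/low at the cut point.

    By default the boundary is assigned to ``high`` (mdNLR >= cutpoint);
    with ``strict`` the comparison is mdNLR > cutpoint.  The labels are
    also stored on the score object.
    """
    if cutpoint <= 0:
        raise ValueError("cutpoint must be positive")
    high = score.mdnlr > cutpoint if strict else score.mdnlr >= cutpoint
    group = pd.Series(
        np.where(high, "high", "low"), index=score.sample_ids, name="mdnlr_group"
    )
    score.group = group
    return group


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def write_library_csv(library: ReferenceLibrary, path) -> None:
    out = library.design.copy()
    out.index.name = "cpg_id"
    out.to_csv(path, float_format="%.6g")


def read_library_csv(path) -> ReferenceLibrary:
    return ReferenceLibrary(design=pd.read_csv(path, index_col=0))


def write_proportions_tsv(props: CellProportionTable, path) -> None:
    out = props.omega.copy()
    out["residual_norm"] = props.residual_norm
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_mdnlr_tsv(score: MdnlrScore, path) -> None:
    out = pd.DataFrame({"mdnlr": score.mdnlr, "floored": score.floored})
    if score.group is not None:
        out["group"] = score.group
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
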