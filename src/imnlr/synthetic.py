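"""Synthetic immunomethylomic cohorts with planted ground truth.

Every downstream stage of the package (QC, deconvolution, mdNLR, surrogate
screening, survival modelling) is exercised against cohorts generated here.
A cohort consists of

* purified-leukocyte reference profiles for six cell types (CD4T, CD8T, B,
  NK, Mono, Gran) with planted leukocyte DMRs (L-DMRs) and planted
  myeloid-demethylated surrogate loci,
* whole-blood beta values formed as noisy convex combinations of those
  profiles with Dirichlet-sampled cell compositions (a case stratum shifted
  toward granulocytes),
* matched detection p-values with a configurable set of failing probes, and
* survival times drawn from an exponential proportional-hazards model with
  planted log hazard ratios and independent censoring.

All generators require an explicit seed and are bit-reproducible given the
same parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .preprocessing import BetaMatrix

# ---------------------------------------------------------------------------
# Study-condition constants
# ---------------------------------------------------------------------------

#: Cell types in fixed order; the last two constitute the myeloid lineage.
CELL_TYPES: tuple[str, ...] = ("CD4T", "CD8T", "B", "NK", "Mono", "Gran")
LYMPHOID_TYPES: tuple[str, ...] = CELL_TYPES[:4]
MYELOID_TYPES: tuple[str, ...] = ("Mono", "Gran")

#: Dirichlet parameters for the two composition strata.  The control stratum
#: reflects a typical adult white-cell differential (granulocytes ~59%,
#: NLR ~ 1.7); the case stratum is shifted toward granulocytes (NLR ~ 4.2)
#: with a higher concentration so the lymphocyte fraction rarely collapses.
CONTROL_ALPHA = 25.0 * np.array([0.16, 0.08, 0.05, 0.05, 0.07, 0.59])
CASE_ALPHA = 60.0 * np.array([0.081, 0.045, 0.027, 0.027, 0.07, 0.75])

#: Lymphoid floor for truth draws: compositions with CD4T+CD8T+B+NK below
#: this are redrawn so the true NLR is always finite.
MIN_LYMPHOID = 0.02

#: Ceiling on the true NLR in the default case/control design, matching the
#: clinically observed range of elevated ratios; draws above it are redrawn.
MAX_TRUE_NLR = 12.0

#: Detection p-value threshold separating passing from failing probe calls.
DETECTION_P_THRESHOLD = 1e-5

#: Beta-scale array noise (truncated-Gaussian SD).
DEFAULT_NOISE_SD = 0.015

#: Planted log hazard ratios: high mdNLR doubles the hazard, TERT-only
#: mutation multiplies it by 4.5.
DEFAULT_LOG_HRS: dict[str, float] = {
    "mdnlr_high": math.log(2.0),
    "tert_only": math.log(4.5),
}


def _require_seed(seed) -> int:
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    return int(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTruth:
    """Purified-cell methylation profiles with planted marker structure.

    ``profiles`` is a CpG x cell-type DataFrame of mean beta values.
    ``ldmr_ids`` are the planted leukocyte DMRs (``ldmr_by_type`` maps each
    cell type to its uniquely hypo-/hyper-methylated CpGs); ``surrogate_ids``
    are the planted myeloid-demethylated mdNLR surrogates.
    """

    cell_types: tuple[str, ...]
    profiles: pd.DataFrame
    ldmr_ids: list[str]
    ldmr_by_type: dict[str, list[str]]
    surrogate_ids: list[str]
    seed: int

    @property
    def cpg_ids(self) -> pd.Index:
        return self.profiles.index

    @property
    def background_ids(self) -> list[str]:
        special = set(self.ldmr_ids) | set(self.surrogate_ids)
        return [c for c in self.profiles.index if c not in special]


@dataclass
class TrueComposition:
    """Ground-truth cell compositions on the unit simplex."""

    proportions: pd.DataFrame  # sample x cell type, rows sum to 1
    true_nlr: pd.Series  # Gran / (CD4T+CD8T+B+NK)
    strata: pd.Series | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.proportions.index

    def __post_init__(self) -> None:
        rows = self.proportions.to_numpy()
        if (rows < 0).any():
            raise ValueError("compositions must be nonnegative")
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1")


@dataclass
class PurifiedReference:
    """Synthetic purified-leukocyte samples with donor blood differentials.

    Emulates a flow-sorted reference panel: each donor contributes one
    sample per cell type at 97-99.5% purity (typical of magnetically or
    flow-sorted leukocytes); ``measured_props`` holds the
    donor's whole-blood differential (shared across that donor's samples),
    the covariate the lineage model adjusts for.
    """

    beta: BetaMatrix
    cell_labels: pd.Series  # sample -> cell type
    lineage_labels: pd.Series  # sample -> {myeloid, lymphoid}
    measured_props: pd.DataFrame  # sample x cell type (donor differential)
    true_props: pd.DataFrame  # sample x cell type (actual sample content)


@dataclass
class SyntheticCohort:
    """A complete synthetic study: data as observed plus the planted truth."""

    beta: BetaMatrix
    covariates: pd.DataFrame  # sample_id-indexed: age, sex, grade, mutation
    time: pd.Series
    event: pd.Series
    truth: ReferenceTruth
    composition: TrueComposition
    purified: PurifiedReference
    log_hrs: dict[str, float] = field(default_factory=dict)
    failing_ids: list[str] = field(default_factory=list)

    @property
    def records(self) -> pd.DataFrame:
        """Covariates + outcome in one frame (survival-module input)."""
        out = self.covariates.copy()
        out["time"] = self.time
        out["event"] = self.event
        return out


# ---------------------------------------------------------------------------
# Reference profiles
# ---------------------------------------------------------------------------


def generate_reference_profiles(
    n_cpgs: int,
    n_ldmr_per_type: int = 50,
    n_surrogates: int = 5,
    seed: int | None = None,
) -> ReferenceTruth:
    """Generate purified-cell mean-beta profiles with planted markers.

    Each cell type receives ``n_ldmr_per_type`` CpGs uniquely hypo- or
    hyper-methylated relative to all other types (|delta beta| >= 0.3,
    split evenly between the two directions).  ``n_surrogates`` CpGs are
    demethylated in both myeloid types (beta ~ 0.03-0.10) and methylated in
    all lymphoid types (beta ~ 0.85-0.95), so their mixture methylation
    tracks the myeloid fraction.  Remaining CpGs share one common mean
    across all types.
    """
    seed = _require_seed(seed)
    n_special = n_ldmr_per_type * len(CELL_TYPES) + n_surrogates
    if n_special > n_cpgs:
        raise ValueError(
            f"{n_special} marker CpGs requested but universe has only {n_cpgs}"
        )
    rng = np.random.default_rng(seed)
    cpg_ids = np.array([f"cg{i:08d}" for i in range(n_cpgs)])

    profiles = np.empty((n_cpgs, len(CELL_TYPES)))
    # Background: one common mean per CpG, identical across cell types.
    profiles[:] = rng.uniform(0.10, 0.90, size=n_cpgs)[:, None]

    order = rng.permutation(n_cpgs)
    pos = 0
    ldmr_by_type: dict[str, list[str]] = {}
    for k, cell in enumerate(CELL_TYPES):
        idx = order[pos : pos + n_ldmr_per_type]
        pos += n_ldmr_per_type
        n_hypo = (n_ldmr_per_type + 1) // 2
        hypo, hyper = idx[:n_hypo], idx[n_hypo:]
        delta = rng.uniform(0.30, 0.38, size=n_hypo)
        base = rng.uniform(0.45, 0.75, size=n_hypo)
        profiles[hypo] = base[:, None]
        profiles[hypo, k] = base - delta
        delta = rng.uniform(0.30, 0.38, size=len(hyper))
        base = rng.uniform(0.15, 0.45, size=len(hyper))
        profiles[hyper] = base[:, None]
        profiles[hyper, k] = base + delta
        ldmr_by_type[cell] = sorted(cpg_ids[idx])

    sur_idx = order[pos : pos + n_surrogates]
    lo = rng.uniform(0.03, 0.10, size=n_surrogates)
    hi = rng.uniform(0.85, 0.95, size=n_surrogates)
    profiles[sur_idx] = hi[:, None]
    for j, cell in enumerate(CELL_TYPES):
        if cell in MYELOID_TYPES:
            profiles[sur_idx, j] = lo

    profiles = np.clip(profiles, 0.0, 1.0)
    frame = pd.DataFrame(profiles, index=cpg_ids, columns=list(CELL_TYPES))
    ldmr_ids = sorted(c for ids in ldmr_by_type.values() for c in ids)
    return ReferenceTruth(
        cell_types=CELL_TYPES,
        profiles=frame,
        ldmr_ids=ldmr_ids,
        ldmr_by_type=ldmr_by_type,
        surrogate_ids=sorted(cpg_ids[sur_idx]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Compositions
# ---------------------------------------------------------------------------


def _draw_simplex(
    rng: np.random.Generator,
    alpha: np.ndarray,
    n: int,
    min_lymphoid: float,
    max_nlr: float | None = None,
) -> np.ndarray:
    """Dirichlet draws with rejection below the lymphoid floor (and, when
    requested, above the NLR ceiling)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (len(CELL_TYPES),):
        raise ValueError(f"alpha must have length {len(CELL_TYPES)}")
    if (alpha <= 0).any():
        raise ValueError("all Dirichlet alpha must be positive")
    out = np.empty((n, len(CELL_TYPES)))
    need = np.arange(n)
    for _ in range(1000):
        draws = rng.dirichlet(alpha, size=len(need))
        out[need] = draws
        lymph = out[need, :4].sum(axis=1)
        bad = lymph < min_lymphoid
        if max_nlr is not None:
            bad |= out[need, 5] > max_nlr * lymph
        need = need[bad]
        if len(need) == 0:
            return out
    raise RuntimeError("composition rejection sampling did not terminate")


def sample_compositions(
    n_samples: int,
    alpha: Mapping[str, Sequence[float]] | Sequence[float],
    strata: Sequence[str] | None = None,
    seed: int | None = None,
    min_lymphoid: float = MIN_LYMPHOID,
    max_nlr: float | None = None,
) -> TrueComposition:
    """Sample per-stratum Dirichlet compositions with a lymphoid floor.

    ``alpha`` is either a single 6-vector (one stratum) or a mapping from
    stratum label to 6-vector, in which case ``strata`` gives each sample's
    label.  Rows whose lymphoid sum falls below ``min_lymphoid`` are
    redrawn, so the true NLR (Gran over summed lymphocytes) is finite;
    with ``max_nlr`` set, rows whose NLR exceeds it are redrawn too,
    bounding the support of the composition distribution.
    """
    seed = _require_seed(seed)
    rng = np.random.default_rng(seed)
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n_samples)], name="sample_id")

    if isinstance(alpha, Mapping):
        if strata is None:
            raise ValueError("per-stratum alpha requires per-sample strata labels")
        strata = pd.Series(list(strata), index=sample_ids, name="stratum")
        props = np.empty((n_samples, len(CELL_TYPES)))
        for label in pd.unique(strata):
            mask = (strata == label).to_numpy()
            props[mask] = _draw_simplex(
                rng, np.asarray(alpha[label], float), int(mask.sum()),
                min_lymphoid, max_nlr,
            )
    else:
        props = _draw_simplex(
            rng, np.asarray(alpha, float), n_samples, min_lymphoid, max_nlr
        )
        strata = None

    frame = pd.DataFrame(props, index=sample_ids, columns=list(CELL_TYPES))
    nlr = frame["Gran"] / frame[list(LYMPHOID_TYPES)].sum(axis=1)
    return TrueComposition(proportions=frame, true_nlr=nlr.rename("true_nlr"), strata=strata)


def case_control_composition(
    n_samples: int,
    case_fraction: float = 0.5,
    seed: int | None = None,
) -> TrueComposition:
    """Default two-stratum design: controls (NLR ~ 2) and cases (NLR ~ 4-6)."""
    n_case = int(round(n_samples * case_fraction))
    strata = ["control"] * (n_samples - n_case) + ["case"] * n_case
    return sample_compositions(
        n_samples,
        alpha={"control": CONTROL_ALPHA, "case": CASE_ALPHA},
        strata=strata,
        seed=seed,
        max_nlr=MAX_TRUE_NLR,
    )


def composition_from_nlr(
    nlr_values: Sequence[float],
    mono_fraction: float = 0.07,
    lymph_split: Sequence[float] = (0.45, 0.25, 0.15, 0.15),
) -> TrueComposition:
    """Deterministic titration design realizing prescribed true NLR values.

    For each requested NLR the lymphoid sum is ``(1 - mono) / (1 + NLR)``
    and Gran is ``NLR`` times that, with the lymphoid mass divided in a
    fixed ratio.  Useful for validation cohorts whose NLR must span a
    given range exactly.
    """
    nlr = np.asarray(nlr_values, dtype=float)
    if (nlr < 0).any():
        raise ValueError("NLR values must be nonnegative")
    split = np.asarray(lymph_split, dtype=float)
    lymph = (1.0 - mono_fraction) / (1.0 + nlr)
    gran = nlr * lymph
    props = np.column_stack(
        [lymph[:, None] * split, np.full_like(nlr, mono_fraction), gran]
    )
    sample_ids = pd.Index([f"S{i:04d}" for i in range(len(nlr))], name="sample_id")
    frame = pd.DataFrame(props, index=sample_ids, columns=list(CELL_TYPES))
    return TrueComposition(
        proportions=frame,
        true_nlr=pd.Series(nlr, index=sample_ids, name="true_nlr"),
    )


# ---------------------------------------------------------------------------
# Beta synthesis
# ---------------------------------------------------------------------------


def synthesize_betas(
    truth: ReferenceTruth,
    comp: TrueComposition,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_failing: int = 0,
    fail_fraction: float = 0.3,
    seed: int | None = None,
) -> tuple[BetaMatrix, list[str]]:
    """Mix reference profiles into whole-blood betas plus detection p-values.

    ``beta[j, i] = sum_k profile[j, k] * omega[i, k] + eps`` with
    ``eps ~ N(0, noise_sd^2)``, clipped to [0, 1].  ``n_failing`` background
    probes are planted to fail detection (p above the 1e-5 threshold) in
    strictly more than ``fail_fraction`` of samples; all other detection
    p-values are at or below the threshold.  Returns the matrix and the
    planted failing-probe ids.
    """
    seed = _require_seed(seed)
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)

    profiles = truth.profiles.to_numpy()  # cpg x type
    omega = comp.proportions.to_numpy()  # sample x type
    clean = profiles @ omega.T
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    values = pd.DataFrame(
        np.clip(clean, 0.0, 1.0), index=truth.cpg_ids, columns=comp.sample_ids
    )

    n_samples = len(comp.sample_ids)
    # Passing calls: p well below the 1e-5 threshold.
    detection = 10.0 ** rng.uniform(-9.0, -5.0, size=values.shape)
    failing: list[str] = []
    if n_failing > 0:
        background = truth.background_ids
        if n_failing > len(background):
            raise ValueError("more failing probes requested than background CpGs")
        failing = sorted(rng.choice(background, size=n_failing, replace=False))
        n_bad = int(math.floor(fail_fraction * n_samples)) + 1  # strictly > fraction
        n_bad = min(n_bad, n_samples)
        row_lookup = {c: i for i, c in enumerate(values.index)}
        for cpg in failing:
            cols = rng.choice(n_samples, size=n_bad, replace=False)
            detection[row_lookup[cpg], cols] = rng.uniform(1e-4, 0.9, size=n_bad)
    detection = pd.DataFrame(detection, index=values.index, columns=values.columns)
    return BetaMatrix(values=values, detection_p=detection), failing


def simulate_purified_reference(
    truth: ReferenceTruth,
    n_per_type: int = 9,
    purity_range: tuple[float, float] = (0.97, 0.995),
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
) -> PurifiedReference:
    """Simulate a flow-sorted reference panel (one sample per donor x type).

    Each of ``n_per_type`` donors contributes six purified samples.  A
    sample of type *t* contains a uniform-random purity of *t* with the
    contamination distributed according to the donor's whole-blood
    differential over the other types.  The donor differential (a control-
    stratum Dirichlet draw) is what ``measured_props`` reports — the
    flow-cytometry covariate of the lineage model.
    """
    seed = _require_seed(seed)
    rng = np.random.default_rng(seed)
    n_types = len(CELL_TYPES)
    sample_ids, labels, rows, measured = [], [], [], []
    for d in range(n_per_type):
        blood = _draw_simplex(rng, CONTROL_ALPHA, 1, MIN_LYMPHOID)[0]
        for k, cell in enumerate(CELL_TYPES):
            purity = rng.uniform(*purity_range)
            w = blood.copy()
            w[k] = 0.0
            w = (1.0 - purity) * w / w.sum()
            w[k] = purity
            sample_ids.append(f"P{d:02d}_{cell}")
            labels.append(cell)
            rows.append(w)
            measured.append(blood)
    omega = np.array(rows)
    betas = truth.profiles.to_numpy() @ omega.T
    if noise_sd > 0:
        betas = betas + rng.normal(0.0, noise_sd, size=betas.shape)
    index = pd.Index(sample_ids, name="sample_id")
    beta = BetaMatrix(
        values=pd.DataFrame(np.clip(betas, 0, 1), index=truth.cpg_ids, columns=index)
    )
    cell_labels = pd.Series(labels, index=index, name="cell_type")
    lineage = cell_labels.map(
        lambda c: "myeloid" if c in MYELOID_TYPES else "lymphoid"
    ).rename("lineage")
    return PurifiedReference(
        beta=beta,
        cell_labels=cell_labels,
        lineage_labels=lineage,
        measured_props=pd.DataFrame(measured, index=index, columns=list(CELL_TYPES)),
        true_props=pd.DataFrame(omega, index=index, columns=list(CELL_TYPES)),
    )


# ---------------------------------------------------------------------------
# Covariates and survival
# ---------------------------------------------------------------------------


def simulate_covariates(n_samples: int, seed: int | None = None) -> pd.DataFrame:
    """Cohort covariates: age 40-59, sex, grade (GBM/non-GBM), mutation.

    Marginals mirror a glioma case series restricted to the two mutually
    exclusive mutation subtypes: 72% male, 46% GBM, 58% TERT-only.
    """
    seed = _require_seed(seed)
    rng = np.random.default_rng(seed)
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n_samples)], name="sample_id")
    return pd.DataFrame(
        {
            "age": rng.uniform(40.0, 60.0, n_samples),
            "sex": np.where(rng.random(n_samples) < 0.72, "M", "F"),
            "grade": np.where(rng.random(n_samples) < 0.46, "GBM", "non-GBM"),
            "mutation": np.where(
                rng.random(n_samples) < 0.58, "TERT-only", "IDH-only"
            ),
        },
        index=sample_ids,
    )


def simulate_survival(
    design: pd.DataFrame,
    log_hrs: Mapping[str, float],
    baseline_scale: float = 60.0,
    censor_rate: float = 0.4,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential proportional-hazards event times with independent censoring.

    Event times follow rate ``exp(lp) / baseline_scale`` where the linear
    predictor ``lp`` sums ``log_hr * covariate`` over the named numeric
    columns of ``design``.  Censoring is an independent exponential whose
    rate is calibrated so the expected censored fraction equals
    ``censor_rate``.  Returns a frame with ``time`` (months) and ``event``.
    """
    seed = _require_seed(seed)
    if baseline_scale <= 0:
        raise ValueError("baseline_scale must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    missing = [c for c in log_hrs if c not in design.columns]
    if missing:
        raise ValueError(f"log_hrs name columns absent from design: {missing}")
    rng = np.random.default_rng(seed)

    lp = np.zeros(len(design))
    for col, coef in log_hrs.items():
        lp = lp + coef * design[col].to_numpy(dtype=float)
    rates = np.exp(lp) / baseline_scale
    event_times = rng.exponential(1.0 / rates)

    if censor_rate == 0:
        time, event = event_times, np.ones(len(design), dtype=int)
    else:
        # P(censor | rate_i) = mu / (mu + rate_i); calibrate mu to the mean.
        def expected(log_mu: float) -> float:
            mu = math.exp(log_mu)
            return float(np.mean(mu / (mu + rates))) - censor_rate

        log_mu = brentq(expected, -30.0, 30.0)
        censor_times = rng.exponential(math.exp(-log_mu), size=len(design))
        event = (event_times <= censor_times).astype(int)
        time = np.minimum(event_times, censor_times)
    return pd.DataFrame({"time": time, "event": event}, index=design.index)


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


def generate_cohort(
    n_samples: int = 500,
    n_cpgs: int = 1000,
    n_ldmr_per_type: int = 50,
    n_surrogates: int = 5,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_failing: int = 20,
    fail_fraction: float = 0.3,
    n_purified_per_type: int = 9,
    log_hrs: Mapping[str, float] | None = None,
    baseline_scale: float = 60.0,
    censor_rate: float = 0.4,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a complete synthetic study with planted ground truth.

    GBM cases draw compositions from the granulocyte-shifted case stratum,
    non-GBM from the control stratum, so grade and mdNLR co-vary as in real
    cohorts.  Survival depends on the planted log hazard ratios applied to
    ``mdnlr_high`` (true NLR >= 4) and ``tert_only`` by default.
    """
    seed = _require_seed(seed)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    if log_hrs is None:
        log_hrs = dict(DEFAULT_LOG_HRS)
    else:
        log_hrs = dict(log_hrs)

    truth = generate_reference_profiles(
        n_cpgs, n_ldmr_per_type, n_surrogates, seed=seeds[0]
    )
    covariates = simulate_covariates(n_samples, seed=seeds[1])
    strata = np.where(covariates["grade"] == "GBM", "case", "control")
    comp = sample_compositions(
        n_samples,
        alpha={"control": CONTROL_ALPHA, "case": CASE_ALPHA},
        strata=strata,
        seed=seeds[2],
        max_nlr=MAX_TRUE_NLR,
    )
    beta, failing = synthesize_betas(
        truth,
        comp,
        noise_sd=noise_sd,
        n_failing=n_failing,
        fail_fraction=fail_fraction,
        seed=seeds[3],
    )
    purified = simulate_purified_reference(
        truth, n_per_type=n_purified_per_type, noise_sd=noise_sd, seed=seeds[4]
    )

    design = pd.DataFrame(
        {
            "age": covariates["age"] - 50.0,
            "male": (covariates["sex"] == "M").astype(int),
            "gbm": (covariates["grade"] == "GBM").astype(int),
            "tert_only": (covariates["mutation"] == "TERT-only").astype(int),
            "mdnlr_high": (comp.true_nlr >= 4.0).astype(int),
        },
        index=covariates.index,
    )
    surv = simulate_survival(
        design,
        log_hrs,
        baseline_scale=baseline_scale,
        censor_rate=censor_rate,
        seed=seeds[0] ^ seeds[1],
    )
    return SyntheticCohort(
        beta=beta,
        covariates=covariates,
        time=surv["time"],
        event=surv["event"],
        truth=truth,
        composition=comp,
        purified=purified,
        log_hrs=log_hrs,
        failing_ids=failing,
    )
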