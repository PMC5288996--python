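"""End-to-end orchestration: one config, all stages, a reproducible report.

The pipeline sequences QC -> deconvolution -> mdNLR -> surrogate screening
-> survival modelling, either on a generated synthetic cohort (seed
required) or on user-supplied delimited-text matrices.  Every stage writes
its tabular intermediates to the output directory with fixed float
formatting, so reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconvolution, myeloid, preprocessing, survival, synthetic

logger = logging.getLogger("imnlr")

BASELINE_COVARIATES = ["age", "male", "gbm", "tert_only"]


@dataclass
class PipelineConfig:
    """All knobs of a run.  Exactly one of ``paths``/``synthetic`` is set."""

    output_dir: str = "imnlr_out"
    paths: dict | None = None  # beta, detection_p, reference, covariates
    synthetic: dict | None = None  # generate_cohort kwargs (seed required)
    p_threshold: float = preprocessing.DEFAULT_P_THRESHOLD
    sample_fraction: float = preprocessing.DEFAULT_SAMPLE_FRACTION
    n_per_type: int = 50
    cutpoint: float = deconvolution.DEFAULT_CUTPOINT
    strict_cutpoint: bool = False
    lymph_floor: float = deconvolution.DEFAULT_LYMPH_FLOOR
    normalize_proportions: bool = False
    top_k: int = myeloid.DEFAULT_TOP_K
    degrees: tuple[int, ...] = myeloid.DEFAULT_DEGREES
    adj_r2_threshold: float = myeloid.DEFAULT_ADJ_R2_THRESHOLD

    def __post_init__(self) -> None:
        if (self.paths is None) == (self.synthetic is None):
            raise ValueError("exactly one of paths/synthetic must be configured")
        if self.synthetic is not None and "seed" not in self.synthetic:
            raise ValueError("synthetic mode requires a seed")
        if not 0 < self.sample_fraction < 1 or not 0 < self.p_threshold < 1:
            raise ValueError("QC thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "degrees" in raw:
            raw["degrees"] = tuple(raw["degrees"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(name: str, config: PipelineConfig) -> None:
    logger.info("stage=%s config_digest=%s", name, config.digest())


def summarize_cohort(records: pd.DataFrame, cutpoint: float = 4.0) -> dict:
    """Cohort characteristics table: n, age, sex/grade/mutation percentages,
    high-mdNLR percentage, follow-up range and median (IQR) survival.

    Percentages are rounded to whole numbers; medians and IQRs to two
    decimals.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")

    def med_iqr(x: pd.Series) -> str:
        q1, q2, q3 = np.percentile(x, [25, 50, 75])
        return f"{q2:.2f} ({q1:.2f}, {q3:.2f})"

    pct = lambda mask: int(round(100.0 * float(np.mean(mask))))
    out = {
        "n": int(len(records)),
        "median_age_iqr": med_iqr(records["age"]),
        "pct_male": pct(records["sex"] == "M"),
        "pct_gbm": pct(records["grade"] == "GBM"),
        "pct_tert_only": pct(records["mutation"] == "TERT-only"),
        "followup_range_months": f"{records['time'].min():.2f}-{records['time'].max():.2f}",
        "median_survival_iqr": med_iqr(records["time"]),
    }
    if "mdnlr" in records:
        out[f"pct_mdnlr_ge_{cutpoint:g}"] = pct(records["mdnlr"] >= cutpoint)
    return out


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        cohort = synthetic.generate_cohort(**config.synthetic)
        return cohort.beta, cohort.purified, cohort.records, cohort
    paths = config.paths
    beta = preprocessing.read_beta_csv(paths["beta"], paths.get("detection_p"))
    ref = preprocessing.read_beta_csv(paths["reference"])
    labels = pd.Series(
        {s: s.rsplit("_", 1)[-1] for s in ref.sample_ids}, name="cell_type"
    )
    lineage = labels.map(
        lambda c: "myeloid" if c in synthetic.MYELOID_TYPES else "lymphoid"
    )
    covars = pd.read_csv(paths["covariates"], index_col=0)
    purified = synthetic.PurifiedReference(
        beta=ref,
        cell_labels=labels,
        lineage_labels=lineage,
        measured_props=pd.read_csv(paths["measured_props"], index_col=0)
        if "measured_props" in paths
        else pd.DataFrame(),
        true_props=pd.DataFrame(),
    )
    return beta, purified, covars, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write intermediates, return the run report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = {"sep": "\t", "float_format": "%.6g"}

    _stage("inputs", config)
    beta, purified, records, cohort = _load_inputs(config)

    _stage("qc", config)
    if beta.detection_p is not None:
        beta, removal_log = preprocessing.filter_detection_p(
            beta, config.p_threshold, config.sample_fraction
        )
        preprocessing.write_removal_log(removal_log, outdir / "qc_removal_log.tsv")

    _stage("deconvolution", config)
    library = deconvolution.select_reference_library(
        purified.beta, purified.cell_labels, n_per_type=config.n_per_type
    )
    deconvolution.write_library_csv(library, outdir / "reference_library.csv")
    props = deconvolution.estimate_proportions(
        beta, library, normalize=config.normalize_proportions
    )
    deconvolution.write_proportions_tsv(props, outdir / "proportions.tsv")

    _stage("mdnlr", config)
    score = deconvolution.compute_mdnlr(props, floor=config.lymph_floor)
    deconvolution.dichotomize_mdnlr(
        score, cutpoint=config.cutpoint, strict=config.strict_cutpoint
    )
    deconvolution.write_mdnlr_tsv(score, outdir / "mdnlr.tsv")

    _stage("surrogates", config)
    m_purified = preprocessing.beta_to_m(purified.beta.values)
    lineage_stats = myeloid.fit_lineage_model(
        m_purified, purified.lineage_labels, purified.measured_props
    )
    lineage_out = lineage_stats.copy()
    lineage_out.index.name = "cpg_id"
    lineage_out.to_csv(outdir / "lineage_stats.tsv", **fmt)
    top = myeloid.select_top_loci(lineage_stats, k=min(config.top_k, len(lineage_stats)))
    m_cohort = preprocessing.beta_to_m(beta.values)
    candidates = [c for c in top if c in m_cohort.index]
    surrogate_table = myeloid.screen_surrogates(
        score.mdnlr, m_cohort, candidates, degrees=config.degrees
    )
    selected = myeloid.select_consistent_surrogates(
        [surrogate_table], threshold=config.adj_r2_threshold
    )
    surrogate_table["selected"] = surrogate_table.index.isin(selected)
    surrogate_table.to_csv(outdir / "surrogates.tsv", **fmt)

    group_summary = myeloid.compare_groups_by_locus(
        beta, score.group, loci=selected if selected else candidates[:5]
    )
    group_summary.to_csv(outdir / "locus_group_summary.tsv", **fmt)

    _stage("survival", config)
    records = records.copy()
    records["mdnlr"] = score.mdnlr.reindex(records.index)
    records["mdnlr_high"] = (score.group.reindex(records.index) == "high").astype(int)
    if "male" not in records:
        records["male"] = (records["sex"] == "M").astype(int)
    if "gbm" not in records:
        records["gbm"] = (records["grade"] == "GBM").astype(int)
    if "tert_only" not in records:
        records["tert_only"] = (records["mutation"] == "TERT-only").astype(int)

    univariate = {}
    for cov in [*BASELINE_COVARIATES, "mdnlr_high"]:
        fit = survival.fit_cox(records, [cov])
        univariate[cov] = fit.summary.loc[cov].to_dict()
    baseline = survival.fit_cox(records, BASELINE_COVARIATES)
    augmented = survival.fit_cox(records, [*BASELINE_COVARIATES, "mdnlr_high"])
    lr_stat, lr_df, lr_p = survival.likelihood_ratio_test(augmented, baseline)

    eval_times = np.quantile(
        records.loc[records["event"] == 1, "time"], np.linspace(0.1, 0.8, 8)
    )
    c_base, c_base_se, _ = survival.concordance_from_fit(baseline, records)
    c_aug, c_aug_se, _ = survival.concordance_from_fit(augmented, records)
    _, brier_base = survival.brier_score(
        baseline.predict_survival(records, eval_times), records, eval_times
    )
    _, brier_aug = survival.brier_score(
        augmented.predict_survival(records, eval_times), records, eval_times
    )
    _, auroc_aug = survival.time_dependent_auroc(
        augmented.risk_score(records), records, eval_times
    )
    km = survival.kaplan_meier(
        records.assign(mdnlr_group=np.where(records["mdnlr_high"] == 1, "high", "low")),
        group_by="mdnlr_group",
    )

    model_table = pd.DataFrame(
        {
            "baseline": {
                "c_index": c_base, "c_index_se": c_base_se,
                "brier_integrated": brier_base, "lr_p_vs_baseline": float("nan"),
            },
            "baseline_plus_mdnlr": {
                "c_index": c_aug, "c_index_se": c_aug_se,
                "brier_integrated": brier_aug, "lr_p_vs_baseline": lr_p,
            },
        }
    ).T
    model_table.to_csv(outdir / "model_comparison.tsv", **fmt)
    augmented.summary.to_csv(outdir / "cox_multivariate.tsv", **fmt)

    report = {
        "config_digest": config.digest(),
        "seed": config.synthetic.get("seed") if config.synthetic else None,
        "cohort_summary": summarize_cohort(records, cutpoint=config.cutpoint),
        "univariate_hr": univariate,
        "multivariate_hr": augmented.summary["hr"].round(6).to_dict(),
        "model_comparison": model_table.round(6).to_dict(orient="index"),
        "lr_test": {"stat": round(lr_stat, 6), "df": lr_df, "p": round(lr_p, 6)},
        "tauroc_mdnlr_model": round(auroc_aug, 6),
        "km_median_by_mdnlr_group": km["median"],
        "km_logrank_p": km.get("logrank_p"),
        "n_surrogates_selected": len(selected),
        "selected_surrogates": selected,
    }
    if cohort is not None:
        truth_sel = set(cohort.truth.surrogate_ids)
        report["surrogate_recall"] = (
            len(truth_sel & set(selected)) / len(truth_sel) if truth_sel else None
        )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
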