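# imnlr — immunomethylomic neutrophil-to-lymphocyte ratio

Blood leukocyte composition can be read out from whole-blood DNA
methylation: CpGs that are differentially methylated between leukocyte
subtypes (L-DMRs) act as quantitative lineage markers, and projecting a
blood sample's methylation profile onto purified-cell reference profiles
recovers its cell-type fractions. `imnlr` implements this
"immunomethylomic" workflow for studies of cancer-associated systemic
inflammation, where the neutrophil-to-lymphocyte ratio (NLR) is a
well-replicated prognostic marker: it estimates the **methylation-derived
NLR (mdNLR)** from 450K-style beta values, discovers **single-CpG myeloid
surrogates** of the mdNLR, and relates both to patient survival with Cox
proportional-hazards models and prediction-performance metrics.

It is aimed at epigenetic epidemiologists who have normalized
CpG-by-sample beta matrices (plus detection p-values) and want cell
composition, an inflammation score, and survival models from archival
blood — without fresh cells or flow cytometry.

## The method

1. **QC.** CpGs with detection *p* > 1e-5 in strictly more than 25% of
   samples are removed.
2. **Reference library.** From purified-leukocyte profiles of six cell
   types (CD4T, CD8T, B, NK, Mono, Gran), the top L-DMRs per type are
   chosen by one-vs-rest *t*-statistics on M-values
   (M = log2(β/(1−β))), 50 per type → 300 L-DMRs.
3. **Deconvolution.** Per sample, cell fractions ω̂ solve
   min‖y − Xω‖² subject to ω ≥ 0, Σω ≤ 1, where X is the L-DMR ×
   cell-type mean-beta design matrix (constrained projection).
4. **mdNLR.** mdNLR<sub>i</sub> = ω̂(Gran, i) / ω̂(Lymph, i) with
   Lymph = CD4T+CD8T+B+NK (monocytes enter neither term); samples are
   dichotomized at mdNLR ≥ 4, the elevated-NLR convention.
5. **Myeloid surrogates.** Per-CpG linear models of purified-cell
   M-values on a myeloid/lymphoid indicator (adjusted for measured blood
   composition) rank lineage-specific loci; the top 100 are screened as
   polynomial (degree 1–3) predictors of the mdNLR, keeping loci with
   adjusted R² ≥ 0.80 in every evaluated dataset.
6. **Survival.** Cox models (Efron ties) with age, sex, grade and
   mutation subtype as the clinical baseline; mdNLR group or single-CpG
   M-value terms as the experimental additions. Model comparison uses
   Harrell's c-index, the IPCW Brier score, cumulative/dynamic IPCW
   time-dependent AUROC and partial-likelihood-ratio tests;
   proportionality is checked by the Grambsch–Therneau test on scaled
   Schoenfeld residuals.

A fully specified synthetic-cohort generator (`imnlr.synthetic`) plants
ground truth for every stage — reference profiles with L-DMRs and
myeloid-demethylated surrogate loci, Dirichlet-sampled compositions with
a granulocyte-shifted case stratum, failing probes, and exponential
proportional-hazards survival with planted hazard ratios — so the whole
pipeline is testable without any data download.

## Worked example

```python
import numpy as np
import imnlr

cohort = imnlr.generate_cohort(n_samples=200, seed=7)

beta, qc_log = imnlr.filter_detection_p(cohort.beta)
library = imnlr.select_reference_library(
    cohort.purified.beta, cohort.purified.cell_labels, n_per_type=50
)
props = imnlr.estimate_proportions(beta, library)
score = imnlr.compute_mdnlr(props)
group = imnlr.dichotomize_mdnlr(score, cutpoint=4.0)

rec = cohort.records
rec["male"] = (rec.sex == "M").astype(int)
rec["gbm"] = (rec.grade == "GBM").astype(int)
rec["tert_only"] = (rec.mutation == "TERT-only").astype(int)
rec["mdnlr_high"] = (group == "high").astype(int)
base = imnlr.fit_cox(rec, ["age", "male", "gbm", "tert_only"])
aug = imnlr.fit_cox(rec, ["age", "male", "gbm", "tert_only", "mdnlr_high"])
```

This prints (via the obvious `print` statements):

```
QC removed 20 of 1000 CpGs
library size: 300 L-DMRs
fraction MAE vs truth: 0.0053
Pearson r(mdNLR, true NLR): 0.993
high-mdNLR samples: 66 of 200
mdNLR-high HR 1.96 (95% CI 1.20-3.18), p=0.0067
c-index 0.674 -> 0.692, LR test p=0.0064
```

Reading the numbers: the 20 planted failing probes are exactly the ones
QC removes; estimated cell fractions are within half a percentage point
of the planted compositions on average, so the mdNLR tracks the true NLR
almost perfectly (r = 0.993). The cohort's planted hazard ratio of 2.0
for the high-mdNLR group is recovered at 1.96 after adjustment for age,
sex, grade and mutation subtype, and adding the mdNLR to the clinical
baseline improves model fit (likelihood-ratio p = 0.006) with a higher
concordance — the pattern the method is designed to detect.

The same workflow runs from the shell on delimited-text matrices:

```bash
imnlr run --config config.yaml          # full pipeline, synthetic or file-based
imnlr simulate --config config.yaml     # write a synthetic cohort to CSV
imnlr qc --beta beta.csv --detection-p p.csv --out qc/
imnlr deconvolve --beta beta.csv --library library.csv --out deconv/
imnlr survive --records records.csv --formula age,male,gbm,tert_only,mdnlr_high
```

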