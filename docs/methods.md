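# Methods

This note documents the models, estimators and numerical choices behind
`imnlr`, what the synthetic-data generator does and does not emulate, and
the package's known limitations.

## Mixture model and constrained projection

Whole-blood methylation at CpG *j* in sample *i* is modelled as a convex
combination of purified cell-type means plus array noise,

    β_ji = Σ_k X_jk ω_ik + ε_ji,   ω_ik ≥ 0,  Σ_k ω_ik ≤ 1,

with X the L-DMR × cell-type design matrix and k ranging over CD4T,
CD8T, B, NK, Mono, Gran. Per sample, ω̂ minimizes the squared residual
over the constraint set. The solver works on the precomputed quadratic
form (XᵀX, Xᵀy), so cost per sample is independent of library size, and
uses SLSQP with an analytic gradient, a deterministic start at the
centroid of the feasible region, and an objective tolerance of 1e-12
(well inside the 1e-9 contract). On random three-component instances the
solution is optimal to within 1e-6 of an exhaustive grid search at step
0.005 (see `tests/test_acceptance.py`).

The constraint set allows Σω < 1 (unassigned signal absorbs reference
mismatch); an optional post-hoc normalization rescales rows to the
simplex. The mdNLR is a ratio, so it is invariant to that rescaling —
the default computes it from raw ω̂.

Library selection ranks CpGs per cell type by the magnitude of the Welch
one-vs-rest t-statistic on M-values and takes the winners split evenly
between hyper- and hypomethylated directions (backfilling from the other
direction when one side is short). This is a transparent stand-in for
optimized-library searches: with clearly lineage-specific reference
profiles the two approaches select essentially the same markers, and the
search itself is out of scope here.

## The mdNLR

    mdNLR_i = ω̂(Gran, i) / max(ω̂(CD4T)+ω̂(CD8T)+ω̂(B)+ω̂(NK), floor)

Monocytes appear in neither numerator nor denominator. The denominator
floor (default 1e-4) guarantees a finite score; floored samples are
flagged per sample rather than silently truncated. Dichotomization uses
mdNLR ≥ 4 → "high" by default — 4 is the conventional elevated-NLR cut
point in the clinical literature — with a `strict` flag for the > 4
variant, since both readings circulate; the boundary sample at exactly
4.0 is the only case they disagree on.

## Quality control and value scales

A probe call fails when detection p > 1e-5; a CpG is dropped when its
failure fraction strictly exceeds 0.25 (a probe failing in exactly 25%
of samples is retained — the strict reading of "more than a quarter").
Both thresholds are configurable. Missing beta values are rejected, not
imputed. The M-value transform clips betas into [ε, 1−ε] with ε = 1e-3
before the logit, which bounds |M| by ~10 and makes the transform total;
the inverse transform is exact on the unclipped range, and round-trips
hold to 1e-12.

## Myeloid surrogate screen

Stage 1 fits, per CpG, ordinary least squares of purified-sample
M-values on a myeloid-vs-lymphoid indicator plus the samples' measured
blood cell proportions (one proportion column — the last in the fixed
cell-type order — is dropped to break sum-to-one collinearity; columns
that are constant are absorbed by the intercept). The adjustment
covariates are interpreted as the *donor's* whole-blood differential,
shared across that donor's purified samples: they control donor-level
confounding. Interpreting them instead as per-sample purity would make
them exactly collinear with the lineage indicator through the sum-to-one
identity and absorb all lineage signal — the model would be
unidentifiable. The per-CpG regressions share one design matrix, so the
fit is a single vectorized least-squares solve; it matches statsmodels
OLS coefficient-for-coefficient in the tests.

Stage 2 takes the top k = 100 loci by |t| (descending, ties broken
lexicographically by CpG id — a fixed k rather than an automatic rank
cutoff, since 100 is the figure the screen is defined around, and the
cutoff is configurable).

Stage 3 regresses the mdNLR on each candidate locus's M-values with raw
polynomials of degree 1–3 and computes adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1). Raw (non-orthogonalized) powers are fine
at degree ≤ 3 over the M ranges involved; a conditioning warning fires
if the Vandermonde condition number exceeds 1e8. A locus is selected
when its best-degree adjusted R² is ≥ 0.80 in *every* evaluated dataset;
the multi-dataset consistency requirement is what suppresses borderline
single-cohort false positives. Constant loci yield an undefined R² and
are reported as not selected, with the reason.

Group contrasts (high vs low mdNLR, etc.) report median (IQR) beta on
the percentage scale with a two-sided Mann-Whitney U test — exact when
both groups have ≤ 20 samples, normal approximation otherwise.

## Survival models and metrics

Cox models maximize the Efron-tied partial likelihood (delegated to
lifelines, Newton precision 1e-10 so tiny-fixture coefficients agree
with a brute-force one-dimensional maximizer to 1e-6). Coefficients with
|coef| > 20 are flagged as likely separation. The clinical baseline is
age + sex + grade + mutation subtype; experimental models add the mdNLR
group, the continuous mdNLR, or locus M-value terms (including
quadratics).

* **Proportionality** — Grambsch–Therneau score test on scaled
  Schoenfeld residuals against event time (identity transform),
  per-covariate and global; for one covariate the two coincide.
* **Concordance** — Harrell's c over comparable pairs (earlier time an
  observed event, times distinct; tied scores count ½), with the
  pair-based SE √(c(1−c)/n_pairs).
* **Brier score** — IPCW prediction error with Kaplan-Meier censoring
  weights: events before t weighted by 1/G(T⁻), survivors by 1/G(t);
  evaluation times where G vanishes are dropped with a warning;
  integrated score by trapezoid over the retained grid.
* **Time-dependent AUROC** — cumulative-case / dynamic-control
  definition with the same IPCW weights; the grid summary is the
  unweighted mean. This is the standard IPCW estimator family; exact
  published variants differ in integration weights and truncation, which
  are not pinned down here, so the tests cross-check both metrics
  against scikit-survival's implementations rather than against any one
  paper's variant.
* **Model comparison** — partial-likelihood ratio test between nested
  fits on identical records (χ² with df = parameter difference).
  Group-wise log-rank tests are reserved for Kaplan-Meier comparisons.

Kaplan-Meier medians use the earliest time with S(t) ≤ 0.5 and are
reported as not reached (infinity) when the curve never crosses ½.

## What the synthetic cohort emulates

The generator is the package's test bed and defines its study
conditions:

* **Reference profiles.** Six cell types; 50 L-DMRs per type, uniquely
  hypo-/hyper-methylated with |Δβ| ∈ [0.30, 0.38] against a common
  background; surrogate loci demethylated in both myeloid types
  (β ≈ 0.03–0.10) and methylated in all lymphoid types (β ≈ 0.85–0.95),
  the magnitude typical of lineage-commitment demethylation. Background
  CpGs share one mean across types, so they carry no composition signal.
* **Compositions.** Dirichlet draws from two strata: controls around a
  normal adult differential (mean NLR ≈ 1.7, concentration 25) and a
  granulocyte-shifted case stratum (mean NLR ≈ 4.2, concentration 60).
  Draws are rejected below a lymphoid floor of 0.02 (keeping the true
  NLR finite) and above a true-NLR ceiling of 12, the clinically
  observed range of elevated ratios; without the ceiling, rare draws
  with lymphocytes under ~5% produce single samples of extreme leverage
  that no ratio-outcome regression survives. A deterministic titration
  design (`composition_from_nlr`) realizes any prescribed NLR values
  exactly, for validation cohorts that must span a stated range.
* **Arrays.** β = profile mixture + additive Gaussian noise
  (SD 0.015 by default, in the published range of 450K
  technical-replicate variability), clipped to [0,1]; the clipping keeps
  the convex-mixture identity exact at zero noise. Planted failing
  probes receive detection p > 1e-5 in strictly more than the configured
  fraction of samples.
* **Purified panel.** Nine donors × six types at 97–99.5% purity (sorted
  leukocyte panels are this clean; heavier contamination measurably
  biases the estimated reference means and, through them, the mdNLR
  upward), contamination proportional to the donor's blood differential;
  the donor differential is what the lineage model adjusts for.
* **Survival.** Exponential proportional hazards with baseline scale 60
  months, planted log hazard ratios (high mdNLR: log 2; TERT-only
  mutation: log 4.5), and independent exponential censoring calibrated
  so the expected censored fraction matches the requested rate (default
  0.40). Grade GBM ties to the case composition stratum, so mdNLR and
  grade co-vary as in real cohorts.

Not emulated: Infinium I/II probe chemistry and normalization, batch or
chip structure, SNP-affected probes, age-associated drift, competing
risks, and non-proportional hazards. Passing tests therefore demonstrate
correctness of the estimators under the mixture-plus-noise model, not
robustness to array artifacts — real data should arrive normalized and
batch-corrected, which is an explicit input assumption.

## Problem sizes used in the checks

The test-bed cohorts use 1000 CpGs (300 L-DMRs, 5 surrogates, 20 failing
probes) with 50–500 samples; hazard-ratio recovery and coverage use 100
replicate cohorts of n = 500 at ~40% censoring; the surrogate screen
runs 20 independent three-cohort experiments; metric calibration checks
use 200 replicates. These sizes put Monte-Carlo error well inside the
asserted bands while keeping the full suite under a few minutes.

## Limitations

* The reference library is selected by t-statistics, not by a
  combinatorial library optimization; with weakly separated reference
  profiles the two can diverge.
* The mdNLR inherits ratio pathology: when the estimated lymphoid sum
  approaches zero the score explodes, which is why the floor, the flag,
  and the composition-support bounds exist. Analyses of heavily
  lymphodepleted cohorts should treat extreme scores with care.
* The c-index SE is the simple pair-based estimator, anti-conservative
  under heavy censoring.
* Single-locus surrogates are screened against the mdNLR, not against
  outcome; their survival associations are assessed separately in the
  Cox layer, and nothing here establishes causality.
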