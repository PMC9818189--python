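# Methods

## The deconvolution model

A bulk expression profile is modelled as a convex combination of cell-type
expression profiles. Given a signature matrix `S` (marker genes × K cell
types, non-negative) and a bulk vector `b` restricted to the genes shared
with `S`, the engine solves a regression of `b` on the columns of `S`,
clips negative coefficients to zero, and reports

* **fractions** — clipped coefficients divided by their sum. Rows sum to
  one (within 1e-9) and are invariant to positive rescaling of `b`. A
  sample whose coefficients are all zero (nothing in the reference explains
  it) falls back to uniform fractions with a logged warning rather than an
  undefined vector; its fit statistics expose the failure.
* **abundance scores** — the clipped, un-normalised coefficients. These
  scale with the bulk sample (doubling the sample doubles the scores) and
  are comparable across samples for one cell type, but not across types.
  The distinction matters: when a dominant type collapses (hepatocytes in
  liver cancer), *fractions* of trace types necessarily inflate even if
  their absolute abundance is unchanged.

Two engines share this contract:

* `nnls` — non-negative least squares (`scipy.optimize.nnls`). Exact on
  noiseless mixtures; used as the oracle mode in testing.
* `nu-svr` — linear-kernel nu-support-vector regression. Signature columns
  and the bulk vector are z-scored over the shared genes; nu is swept over
  {0.25, 0.5, 0.75} and the fit with the lowest reconstruction RMSE (after
  mapping coefficients back to the original scale and clipping) is kept,
  per sample. C is 1.0 by default. The sweep-and-pick-by-RMSE convention
  follows the established SVR deconvolution tools. On noiseless mixtures
  the two engines agree to within 0.02 per fraction.

Genes present on only one side are dropped (intersection, no imputation);
the intersection size is logged, and per-sample RMSE and Pearson r between
the reconstruction `S f` and `b` flag samples the reference covers poorly.
Mixtures may legitimately contain cell types absent from the reference
("partial deconvolution"); no explicit unknown component is modelled, the
fit statistics carry that information instead.

## Signature construction

Profiles are arithmetic per-type means of depth-normalised expression
(10,000 counts/cell), not medians. Marker selection:

* **S mode** (single-cell reference): for each type, a one-vs-rest
  two-sided Wilcoxon rank-sum test per gene; Benjamini–Hochberg correction
  within each type's test family; a gene becomes a candidate for the type
  in which its mean is highest when q < 0.3 and the enrichment is positive.
* **B mode** (collapsed-bulk reference): the matrix is collapsed to
  per-type means first, so no cell-level test exists; candidates are genes
  whose profile exceeds the mean of the other types by ≥ 2-fold.

Candidates are ranked by log2 fold change (tie-break: gene order, stable).
The number of genes kept per type, G, is swept from 50 to 150 (or to the
candidate-list length when shorter) and the G minimising the 2-norm
condition number of the resulting matrix is kept — an ill-conditioned
signature amplifies noise in the regression. These constants (q < 0.3,
G ∈ [50, 150], min 20 cells/type) are this package's own defaults; the
hosted tools it parallels do not publish theirs. The whole construction is
deterministic: same atlas and parameters, same signature.

## Pseudo-bulk validation

For a target type, the atlas is split into that type versus all remaining
cells pooled as "others"; 10% of each group is subsampled without
replacement (independently per mixture — the per-mixture resampling gives
honest variance across mixtures); each subsample is averaged into a
representative vector; and the mixture is `V_celltype·f + V_others·(100−f)`
with `f` ~ continuous Uniform(0, 100). Accuracy over n mixtures of one
run is summarised by PCC(f, f′), MAE = (1/n)Σ|f′−f| on the 0–100 scale,
and the mean signed error (positive = overestimation); MAE ≥ |signed error|
always. Intra-study validation draws signature and mixtures from the same
atlas (full type coverage); cross-study validation uses a second atlas
sharing the target label, exercising partial deconvolution — on perturbed
sibling atlases the cross-study MAE exceeds the intra-study MAE in the
median over seeds, as expected.

## Survival stratification

Cohorts are ordered by descending fraction of one cell type; every rank
cut from `min_group`:n−`min_group` (default 1, i.e. 1:n−1 … n−1:1) is
scored by the two-group log-rank test (hypergeometric variance with tie
handling over distinct event times; computed by lifelines, verified in the
test suite against an independent risk-set tabulation). If the minimum
p-value is ≤ α = 0.05 the arg-min cut is returned; otherwise the cohort is
split at the median rank (groups differing by at most one). Survival
lengths are converted to months (days ÷ 30.4375, years × 12); Kaplan–Meier
curves use the product-limit estimator (scikit-survival) and are emitted
as step-function coordinates for external plotting.

Numerical choices: samples with tied fractions are kept in a stable
sample_id order and may straddle the cut — a warning is emitted when they
do; a cohort of identical fractions has no meaningful ordering and falls
back to the median split with a warning; a cut whose log-rank test is
undefined contributes p = 1. Optimised splits isolating fewer than 5
samples are flagged (`small_group`) but not overridden.

**No multiple-testing correction is applied across cuts** — the minimum of
n−1 correlated tests is anti-conservative, and under a null generator the
empirical rate of min-p < 0.05 far exceeds 5% (measured at roughly 50–60%
for n = 40). The package reports this property (the acceptance script
recomputes it as `null_min_p_flag_rate_pct`) instead of correcting it,
because the optimised split is a descriptive cohort-separation device, not
a hypothesis test; treat its p-value as exploratory.

## The synthetic-data generator

The generator defines the conditions under which the pipeline is tested:

* **Atlas**: per-gene baseline rates ~ Gamma(2, 1) + 0.05; each leaf type
  receives a disjoint block of `n_markers_per_type` marker genes (default
  20) whose expected expression is `marker_fold_change` × background
  (default 8); subtypes inherit the parent's block and add a private block
  of a quarter of that size, so tree collapsing has measurable
  consequences. Counts are negative binomial with shared overdispersion
  alpha (default 0.5, Var = mu + alpha·mu²) and log-normal library sizes
  (sigma 0.25 around a 2,000-count mean). Defaults were chosen once as a
  mid-density droplet-like regime: strong but not clean markers, realistic
  count noise.
* **Bulk cohorts**: fractions ~ Dirichlet(1, …, 1); bulk = profile matrix ×
  fractions with multiplicative log-normal noise (sigma 0.1 by default,
  mean-preserving; 0 gives the exact convex combination, on which NNLS
  recovery is exact to ≤ 1e-6).
* **Survival**: exponential times with hazard
  `baseline · exp(logHR · fraction)` (baseline 0.02/month); each patient is
  independently censored with probability `censoring_rate` (default 0.2),
  the censoring time uniform on the latent event time.

What the generator does **not** emulate: doublets, ambient RNA,
dropout-rate curves, batch effects between synthetic studies, platform
differences between microarray and RNA-seq, or non-proportional hazards.
Passing validation on this data therefore demonstrates the correctness of
the algorithms — marker recovery, conditioning, exact and noisy mixture
recovery, cut-point search — not the biological fidelity of any particular
real-data deconvolution, which additionally depends on atlas quality and
on how well the reference matches the bulk tissue's condition.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen to
exercise every code path with comfortable statistical margins: atlases of
3–8 types × 60–100 cells × 300–1,000 genes, 30–50 mixtures per validation
run, survival power over 20 simulated cohorts of n = 200 and a null
calibration over 200 cohorts of n = 40. All of these scale linearly in
cells, genes and samples; nothing in the implementation assumes these
sizes.

## Known limitations

* The nu-SVR engine is a from-scratch re-specification of the SVR
  convention used by hosted deconvolution services, not a re-implementation
  of any proprietary pipeline; no cross-platform batch correction between
  signature and mixture is applied, and results on mixed-platform data
  will differ from services that apply one.
* Gene-ID translation uses a user-supplied mapping table; no live lookup.
* Fractions are relative by construction; absolute compositional claims
  require an external anchor.
* The exhaustive cut-point search inherits the anti-conservativeness
  discussed above; its p-values should not be reported as confirmatory.
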