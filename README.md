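# tmedeconv

Profiling the tumour microenvironment (TME) from bulk transcriptomes by
deconvolution against single-cell reference atlases.

Bulk RNA-seq measures a tissue's mixed expression signal; the cellular
composition behind it — hepatocytes, cholangiocytes, stellate cells, immune
subsets and so on in the case of liver tissue — is lost. Given an annotated
scRNA-seq atlas, that composition can be recovered: a **signature matrix**
`S` (marker genes × cell types, the per-type mean expression over selected
markers) turns each bulk sample `b` into a regression problem

    b ≈ S f ,    f ≥ 0,  Σ f = 1

whose coefficient vector `f` estimates the cell-type fractions. `tmedeconv`
implements this workflow end to end for researchers who want a transparent,
scriptable engine rather than a hosted service:

* **atlas** — depth normalisation (10,000 counts/cell), gene-ID mapping,
  duplicate collapsing (MaxMean for microarray, summation for RNA-seq), and
  cell-type-tree collapsing (merging subtypes into major types);
* **signature** — marker selection by one-vs-rest Wilcoxon rank-sum tests
  (BH q < 0.3) with a condition-number minimisation sweep over the number
  of genes kept per type, in single-cell (`S`) and collapsed-bulk (`B`)
  reference modes;
* **deconv** — per-sample fraction estimation by non-negative least squares
  or linear-kernel nu-SVR (nu swept over {0.25, 0.5, 0.75}), plus
  un-normalised SVR *abundance scores* that are comparable across samples;
* **validation** — pseudo-bulk benchmarking: mixtures
  `V_celltype·f + V_others·(100−f)` with preset uniform `f`, scored by
  Pearson correlation (PCC), mean absolute error (MAE, 0–100 scale) and
  error direction, in intra-study and cross-study modes;
* **survival** — cohort stratification by a cell type's estimated fraction:
  every rank split 1:n−1 … n−1:1 is tested by log-rank, the lowest p-value
  wins (median split when nothing reaches α = 0.05), with Kaplan–Meier
  coordinates emitted for plotting;
* **synthetic_data** — negative-binomial atlases with planted fold-change
  markers and subtype structure, plus bulk cohorts whose survival hazard is
  log-linear in one cell-type fraction, so every stage is testable against
  known ground truth.

## Worked example

```python
import numpy as np
from tmedeconv import (AtlasSpec, CohortSpec, build_signature, estimate_fractions,
                       make_atlas, make_cohort, normalize_counts, optimal_split)

atlas = normalize_counts(make_atlas(AtlasSpec(
    n_types=5, n_cells_per_type=100, n_genes=800,
    n_markers_per_type=20, marker_fold_change=8.0, seed=1)))
sig = build_signature(atlas)
print(sig.expr.shape, round(sig.condition_number, 2))

bulk, truth, cohort = make_cohort(CohortSpec(
    n_patients=50, effect_type="type_0",
    log_hazard_ratio_per_unit_fraction=2.0, seed=2), atlas)
est = estimate_fractions(sig, bulk, method="nnls")
print(round(float(np.abs(est.fractions - truth.to_numpy()).max()), 6))

split = optimal_split(truth["type_0"].to_numpy(), cohort, min_group=5)
print(split.strategy, split.cut_rank, round(split.p_value, 4))
```

prints

```
(186, 5) 2.24
0.046978
optimised 26 0.0174
```

The signature keeps 186 markers across 5 types at condition number 2.24;
with multiplicative bulk noise at its default scale (log-normal, sigma 0.1)
the estimated fractions stay within ~0.05 of the planted truth; and the
exhaustive log-rank search finds a significant split (high-fraction group
of 26 patients, p ≈ 0.017) for the cell type whose fraction drives the
simulated hazard (`min_group=5` keeps the search away from degenerate
one-patient groups; see `docs/methods.md` on the search's
anti-conservativeness).

## Command line

The same stages are available as a CLI over tab-delimited files:

```bash
tmedeconv simulate-atlas --n-types 5 --seed 1 --out-prefix work/atlas
tmedeconv build-signature --atlas-expr work/atlas.expr.tsv \
    --atlas-cells work/atlas.cells.tsv --atlas-tree work/atlas.tree.tsv \
    --out work/sig.tsv
tmedeconv simulate-cohort --atlas-expr work/atlas.expr.tsv \
    --atlas-cells work/atlas.cells.tsv --effect-type type_0 \
    --log-hr 2 --seed 2 --out-prefix work/cohort
tmedeconv deconv --signature work/sig.tsv --mixture work/cohort.bulk.tsv \
    --method nnls --out work/fractions.tsv
tmedeconv survival --fractions work/fractions.tsv \
    --survival work/cohort.survival.tsv --cell-type type_0 \
    --out-prefix work/split
```

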