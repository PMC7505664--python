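# Methods

## Problem and model

Common-disease GWAS loci are overwhelmingly non-coding and polygenic; a
standard way to interpret them is to ask in *which cell types* the
associated genes are preferentially expressed. `cellspec` implements a
two-stage approach:

1. **Expression specificity (ES).** For every gene *g* and cell type *c* of
   an annotated expression matrix, compute how concentrated *g*'s expression
   is in *c*. Four complementary metrics are used, each producing a raw
   weight matrix ES_w:

   * **EP** — expression proportion: `EP_gc = mu_gc / sum_c' mu_gc'`, where
     `mu_gc` is the mean log-normalized expression of *g* in *c*. Rows with
     zero total mean are set to 0.
   * **GES** — gene enrichment score:
     `((f_gc + k_f) / (f_g,not-c + k_f)) * ((mu_gc + k_mu) / (mu_g,not-c + k_mu))`,
     with `f_gc` the fraction of cells of type *c* detecting *g* and the
     "not-c" quantities computed over all remaining cells.
   * **NSI** — normalized specificity index: for each ordered pair
     (*c*, *c'*), genes are ranked by descending `(mu_gc + eps)/(mu_gc' + eps)`;
     the ranks are averaged over comparators and rescaled so the most
     specific gene scores 1 and the least specific 0. Requires ≥3 cell
     types.
   * **DET** — differential-expression t: the Welch t-statistic of *g* in
     *c* versus all other cells, floored at 0 (under-expression is not
     specificity).

2. **Combination.** Per metric and cell type, the significant set Gs holds
   genes whose observed ES_w exceeds a label-permutation null (below).
   Within Gs, weights are rank-normalized, `ES_w*(g) = rank_g(ES_w)/|Gs|`
   (0 outside Gs), modelling specificity as linearly increasing within the
   significant set; the final score `ES_mu` is the unweighted mean of
   `ES_w*` over the four metrics, so `ES_mu ∈ [0, 1]` and the "ES genes" of
   a cell type are exactly those with `ES_mu > 0`.

3. **Genetic prioritization.** Gene-level GWAS Z-statistics are regressed on
   each cell type's `ES_mu` (OLS with intercept, optionally with the
   standard gene-level technical covariates: gene size, gene density,
   inverse mean minor allele count and their logs). Only a positive
   coefficient counts as enrichment, so significance is the one-sided upper
   tail of the coefficient's t-distribution, Bonferroni-corrected over the
   cell types of a dataset. Conditional analysis adds the conditioning cell
   types' `ES_mu` columns as covariates; a focal column collinear with the
   conditioning set is reported degenerate with p = 1. The same scores can
   be exported as per-SNP continuous annotations for partitioned-heritability
   tools: each variant receives the maximum `ES_mu` among genes whose
   transcribed region ±100 kb covers it, together with a binary "all genes"
   annotation and the annotation size (the mean of the vector).

4. **Gene-set enrichment.** Whether a fixed gene set (e.g. high-confidence
   disease genes) is preferentially specific to a cell type is tested with a
   one-sided Wilcoxon rank-sum test (normal approximation with tie and
   continuity corrections; members vs all other genes in the dataset),
   optionally cross-checked by an empirical p from label permutations
   drawing null gene sets of identical size. A gene is called *robustly*
   expressed in a cell type when it is nonzero in ≥10% of that type's cells
   (inclusive boundary), and robustly *and specifically* expressed when
   additionally `ES_mu > 0`.

## Permutation null

The null hypothesis is that a gene is no more specific to a cell type than
to a random set of cells of the same size. Each null draw shuffles the
cell-type label vector globally (sampling annotations without replacement,
including the focal type's own labels) and re-scores the metric; all four
metrics and all cell types are evaluated from the same shuffle, which is
both statistically harmless (p-values are computed per metric and cell
type) and computationally decisive, since every metric is a function of the
per-type sufficient statistics (count, sum, sum of squares, detection
count) obtained from three matrix products per shuffle.

One-sided empirical p-values use the add-one estimator
`p = (1 + #{null >= observed}) / (1 + N_null)`. By default the null weights
are **pooled across genes** within a (metric, cell type) pair, raising the
p-value resolution from `1/n_null` to `1/(n_null * n_genes)`; per-gene
nulls are available (`pooled=False`). Pooling treats genes as exchangeable
under the null, which is an approximation for heterogeneous genes; the
enumeration test (below) checks the pooled estimator against exhaustive
enumeration on a small instance.

## Defaults and tunable parameters

| parameter | default | meaning |
|---|---|---|
| `scale` | 10,000 | common transcript count per cell before `log(x+1)` |
| `anova_alpha` | 1e-5 | one-way-ANOVA retention threshold for the sporadic-gene filter |
| `n_null` | 1,000 | label shuffles per significance run |
| `alpha` | 0.05 | per-metric empirical-p threshold defining Gs |
| `adjust` | "none" | Gs membership on raw empirical p or Benjamini–Hochberg-adjusted p (`"bh"`) |
| `pooled` | True | pool null weights across genes within a cell type |
| `ges_pseudo_frac` / `ges_pseudo_mean` | 0.1 / 0.01 | GES pseudo-counts |
| `nsi_eps` | 1e-9 | NSI ratio stabilizer |
| `det_var_floor` | 1e-12 | Welch variance floor (degenerate zero-variance groups) |
| `window_bp` | 100,000 | symmetric SNP-to-gene window (1-based inclusive, clipped at position 1) |

The metric constants (pseudo-counts, epsilon, variance floor) are exposed
through `MetricConfig`; published variants of these metrics differ in such
constants, so any exact numerical comparison with other implementations
must match them. The Gs threshold and null-draw count materially shape
`ES_mu`; reproducing scores from another implementation requires matching
its settings.

## Synthetic data

`simulate_expression` draws counts from a negative binomial parameterized
by mean and dispersion (variance = mu + mu²/theta, default theta = 2,
droplet-like overdispersion). Per-gene baseline means are log-normally
scattered (sigma = 1) around the configured mean (0.5), so the matrix is
sparse and genes are heterogeneous — deliberately stressing the pooled
permutation null. Each cell type receives a disjoint set of exclusive
marker genes whose mean is multiplied by the fold change in that type only.
Reference conditions used by the test suite: 5 types × 200 cells, 2,000
genes, 10 markers per type, 20-fold markers; the regression checks use a
wider design (20 types × 30 cells, 1,000 genes) so that calibration and
power are measured across many simultaneous tests.

What the generator does *not* emulate: correlated marker programs, nested
or hierarchical cell types, batch effects, doublets, ambient RNA, library
size gradients confounded with type. Passing tests therefore demonstrate
correctness of the statistics under the stated model, not robustness to
every artefact of real atlases.

`simulate_gene_stats` produces gene-level Z-statistics that are either null
N(0,1) — the gene-level analogue of a null GWAS with no genetic signal — or
`effect * ES_mu(g, causal_type) + N(0, noise_sd²)`. The optional technical
covariates are drawn independently of z, so covariate adjustment must not
change calibration. `make_correlated_column` appends a decoy cell type
whose `ES_mu` is a convex mixture of a source column and its label-shuffled
copy, with the mixture weight bisected to a target sample correlation —
used to probe conditional analysis.

## Numerical and design choices

* The sporadic-gene ANOVA runs on normalized log values (the matrix in hand
  after normalization); genes with no variance have an undefined F and are
  excluded; cell types with fewer than two cells are dropped from the test
  with a warning.
* Ortholog mapping keeps strictly one-to-one pairs; colliding pairs are
  dropped entirely rather than resolved by expression.
* Rank ties (NSI comparisons, rank normalization, Wilcoxon) use average
  ranks; the `ES_w*` maximum equals 1 whenever the column maximum within Gs
  is unique.
* One-sided regression p-values are floored at the smallest positive float
  rather than reported as 0. Degeneracy (constant or collinear focal
  column) is detected from the residual variation of the focal column after
  projection on the other regressors (relative tolerance 1e-12).
* The SNP-window maximum rule applies to annotation construction only; the
  gene-level regression needs no overlap rule because each gene carries its
  own score.
* Wilcoxon and Mann–Whitney U are the same test; the package uses one
  implementation for both gene-set use cases.
* The prioritization engine is the gene-level regression formulation;
  SNP-level partitioned-heritability fitting (LD scores, baseline model,
  jackknife errors) is out of scope, but the annotation writer emits the
  per-variant files such a tool consumes.

## Problem sizes in the checks

The statistical acceptance checks run at the reference conditions above:
1,000 null shuffles for marker recovery; 500 null-GWAS replicates × 20 cell
types for calibration; 100 replicates for power and conditional analysis;
10,000 permutations against exhaustive enumeration on a 6-cell instance and
against the analytic Wilcoxon on 100–200 synthetic gene sets. These sizes
were chosen so each Monte-Carlo comparison has enough resolution for the
asserted bound (e.g. the exact binomial 99% band for the type-I error at
10,000 tests is roughly [0.044, 0.056]).

## Known limitations

* Pooled nulls assume approximate exchangeability of genes; strongly
  bimodal expression distributions may distort per-gene p-values (use
  `pooled=False` at the cost of resolution).
* The one-sided design cannot detect cell types where *reduced* expression
  of a gene drives risk.
* `ES_mu` values depend on dataset composition (which other cell types are
  present); scores are comparable within a dataset, not across datasets.
* The regression treats genes as independent; gene-gene correlation induced
  by LD in real gene-level statistics is not modelled by the synthetic
  generator.
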