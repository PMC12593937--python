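# Methods

This note documents the models, estimators, defaults and limitations of the
`typestate` package: what the simulator generates, how each feature score
and evaluation metric is defined, and where design choices were genuinely
open.

## Simulator

### Generative model

Cells belong to one of `K` clusters (cell types; default 3) and one of `G`
experimental groups (conditions; default 2), with `R` replicate samples per
group (default 3) and `n_cells_per_sample` cells each (default 200, so
1200 cells). For gene *i* and cell *c*:

```
counts[i, c] ~ Poisson( q[i, c] )
q[i, c]     ~ Gamma( mean = λ_i · lib_c · u[i, s(c)] · FC_type[i, k(c)] · FC_state[i, k(c), g(c)],
                     cv   = bcv )
```

- `λ_i ~ Gamma(shape = 0.6, rate = 2.0)` — per-gene baseline means, giving
  droplet-realistic sparsity (~0.3 counts/gene/cell, ~600 counts per cell
  at 2000 genes).
- `lib_c ~ LogNormal(0, 0.2)` — per-cell library-size factor.
- `u[i, s] ~ LogNormal(0, sample_sigma)`, default 0.3 — per-(gene, sample)
  factors modeling biological sample-to-sample (e.g., subject-to-subject)
  variation. Without this layer, pseudobulk replicates differ only by
  counting noise and differential tests saturate at tiny effects.
- `bcv = 0.3` — biological coefficient of variation of the Gamma-Poisson
  mixing (per-observation overdispersion), in the range routinely estimated
  from droplet data.

### Type and state effects

With probability `p_type` (default 0.3) a gene receives a **type** effect:
for each cluster an independent fold-change `FC ~ LogNormal(t, fc_scale)`
(so `|log FC| = |N(t, fc_scale)|`) with an equiprobable up/down sign on the
log scale. With probability `p_state` (default 0.3) a gene receives a
**state** effect: for each cluster, an independent condition fold-change
drawn the same way with location `s`, applied to every group beyond the
reference. `fc_scale` defaults to 0.4. The two location parameters `t` and
`s` are the axes of the simulation grid; all fold-changes, categories and
scores derive from them.

Gene **categories** (threshold 0 on |log FC| by default): `DE` (any cluster
effect), `DS` (any condition effect), `DEnotDS` / `DSnotDE` (one but not
the other), `DEgtDS` / `DSgtDE` (mean |log FC| of one kind exceeds the
other; type effects are averaged over the K clusters and state effects over
the K·(G−1) non-reference cluster-group slots, and the same convention
defines **true typeness** and **true stateness**).

### What the generator does and does not emulate

The noise layers (sparsity, overdispersion, sample factors) were chosen so
that simulated data sit in the regime the study design presumes: effects at
`t, s ≈ 0.1–0.6` are only partly resolvable by clustering, embeddings built
on variable genes progressively entangle condition signal as `s` grows, and
pseudobulk tests gain power with `s` rather than saturating. Not modelled:
dropout/zero-inflation beyond the Gamma-Poisson form, batch effects
distinct from sample effects, doublets, continuous trajectories, mean-
dependent BCV trends. Consequently, passing tests show that the methods
behave correctly under idealized multi-subject noise — not that they are
robust to ambient RNA, batch chemistry, or annotation errors in real data.

## Standardized processing

Fixed order: QC → normalization → (scoring) → selection → PCA → clustering
→ pseudobulk.

- **QC**: genes detected in `< min_cells_per_gene` cells removed first
  (default 20, the convention for the PBMC dataset this pipeline targets),
  then cells with `< min_genes_per_cell` detected genes (default 1;
  the simulator makes no low-quality cells).
- **Normalization**: `norm = log(1 + counts · median(lib)/lib_c)`, natural
  log. The median-library target makes the scale data-driven; the
  normalized profile of a cell is invariant to its own sequencing depth.
- **PCA**: features centered and scaled to unit variance (ddof 1), exact
  SVD, default 30 components; component signs fixed by forcing the
  largest-magnitude loading positive; constant features dropped with a
  warning.
- **Clustering**: exact kNN graph (Euclidean in PC space, `k = 20`),
  shared-neighbour Jaccard edge weights (neighbourhoods include the cell
  itself), Louvain modularity via igraph at two resolutions — 0.5
  ("low", used for pseudobulk DSA) and 2.0 ("high", used for type/state
  scoring). igraph draws from Python's `random`, which is seeded per call,
  so labels are reproducible. Note that on well-separated data the graph
  decomposes into components and the number of clusters becomes
  insensitive to resolution.
- **Pseudobulk**: per-(sample, cluster) sums of raw counts; empty units are
  absent; column sums conserve the total count.

The initial embedding (before any strategy-specific selection) uses the top
1000 HVGs. The low-resolution default of 0.5 and the 30-PC default are
exposed in `PrepParams` rather than asserted as canonical; both visibly
affect cluster counts and downstream metrics.

## Feature scores

- **hvg** — per-gene variance of log-normalized expression above a fitted
  mean-variance trend. The trend is a tricube-weighted local *quadratic*
  (span 0.3), written in-house because the commonly available lowess
  implementations are local-linear; the biological component (observed −
  trend) may be negative.
- **tF** — moderated F for cluster effects on log-normalized pseudobulk
  expression from high-resolution clusters. Linear model: intercept +
  sample + cluster (sample as fixed blocking effects). Residual variances
  are shrunk by empirical Bayes: the prior `(d0, s0²)` is estimated by
  matching the first two moments of `log s²` to the scaled-F sampling
  distribution (digamma/trigamma inversion; `d0` capped at 1e6, beyond
  which shrinkage is complete). `F = (between-cluster mean square) /
  posterior variance`; `d0 = 0` reproduces the classical F, which the test
  suite verifies against an OLS oracle at 1e-8.
- **tPVE / sPVE** — per-gene variance components of
  `Y ~ (1|sample) + (1|group) + (1|cluster)` on log-normalized expression
  with high-resolution cluster labels; the score is the cluster (type) or
  group (state) share of the total including the residual.
- **sPBDS** — for each low-resolution cluster, sample-level pseudobulks are
  tested across conditions (NB quasi-likelihood, below); p-values are
  BH-adjusted within cluster; `p*` is the per-gene minimum across clusters
  and the score is `−log p*` (natural log; `p*` floored at 1e-300).
- **random** — i.i.d. uniform, seeded; the negative control.

### Variance components

Estimation is REML on collapsed sufficient statistics: cells sharing a
factor combination are reduced to their mean (plus the pooled within-combo
sum of squares), which makes the per-gene problem a ≤ ~50-dimensional one
regardless of cell count. The variance ratios are profiled (the residual
variance has a closed form), and the profiled criterion is minimized per
gene by L-BFGS-B with an analytic gradient, warm-started from a
Henderson-style method-of-moments solution; components below 1e-8 of the
residual are truncated to zero. The method-of-moments path
(`method="mom"`) solves the expected-quadratic-form system for
`R(factor | intercept)` sums of squares in closed form, vectorized across
genes; it is exact ANOVA on balanced designs (verified against closed
forms at 1e-6) but mis-attributes shared variance when factors are
confounded — e.g., when derived clusters absorb the condition — which is
why likelihood-based REML is the default.

### NB quasi-likelihood group test

Used by both `sPBDS` and the DSA engine. Per cluster, with units =
per-sample pseudobulks and offset = log library size:

1. per-gene dispersions maximize the Cox-Reid adjusted profile likelihood
   over a log-spaced grid (1e-4 … 20), then are shrunk 50/50 in log space
   toward a local-linear trend on log mean abundance;
2. full (intercept + group) and null (intercept) GLMs are fitted by
   vectorized IRLS;
3. quasi-dispersions `deviance/df` are EB-squeezed across genes (same
   moment-matching machinery as tF) and the test statistic
   `(dev_null − dev_full) / (df_test · squeezed dispersion)` is referred to
   `F(df_test, d0 + df_resid)`;
4. BH adjustment within cluster; genes with all-zero counts in a cluster
   get p = 1 there.

Clusters lacking two samples in either group are skipped. When *no* cluster
contains both conditions — the typical outcome when the upstream embedding
separates conditions, exactly the pathology this package studies — the test
falls back to whole-dataset sample-level pseudobulks (the coarsest
clustering, labelled `"all"`) so the score and DSA remain defined; the
strict error is available via `fallback_global=False`.

## Selection

Single scores rank genes in decreasing order (fractional ranks for ties;
the final top-n cut breaks ties by gene identifier for cross-platform
reproducibility). Combined strategies use the key
`rank(type) − rank(state)` with ranks assigned in *increasing* score order,
so a gene maximal in type and minimal in state attains the maximal key —
this orientation implements "prioritize high type, low state". When `n` is
not given, it binds to the simulation's `|DEnotDS|`; oracle strategies
return the truth category itself.

## Evaluation metrics

- **ARI** — permutation-model adjusted Rand index (negative values are kept
  in machine-readable output; masking is a display concern).
- **F1** — `TP / (TP + (FP + FN)/2)`; defined as 1 when both sets are
  empty.
- **LISI** — per cell, Gaussian-kernel neighbour weights with the bandwidth
  binary-searched to a target perplexity (default 30; ~90 neighbours);
  `L = 1/Simpson` over category masses. The weighted Simpson concentration
  is debiased by the effective-sample-size correction
  `(Σp² − Σw²)/(1 − Σw²)` so that a perfectly mixed binary labelling reads
  L = 2 rather than ~1.9; the summary is `(mean L − 1)/(n_cat − 1)`,
  clipped to [0, 1].
- **PVE_g / PVE_k** — variance components of `Y ~ (1|g) + (1|k)` per gene,
  re-scaled to sum to one with the residual disregarded; the reported value
  is the mean over the selected genes, skipping genes with both components
  zero.
- **PCR** — per component, the one-way-ANOVA R² of the PC scores on the
  categorical label, averaged with explained-variance weights. A single
  category returns 0 by convention. Under independent labels the null
  value is `(n_categories − 1)/(n_cells − 1)`.
- **Score–truth correlations** — Spearman, each score column against true
  typeness and stateness; constant columns are recorded as 0.

## Workflow and reproducibility

`run_grid` loops (t, s, seed), writing one directory per grid cell with a
JSON manifest; completed cells are skipped on rerun, and per-strategy
failures are isolated and listed in the manifest. Every stochastic stage
consumes a seed derived deterministically (CRC32, < 2³¹) from the master
seed and the cell/stage tags, so any single cell is reproducible in
isolation. Outputs are plain text: MatrixMarket counts, TSV metadata,
truth, score, evaluation and p* tables.

The desk-scale study used throughout the tests runs the reduced grid
`t, s ∈ {0.2, 0.6, 1.0}` with two replicate simulations per cell at the
default 2000 genes × 1200 cells — the smallest design that still spans the
weak/strong corners of both axes with a middle point.

## Known limitations

- With `K = 3`, the cluster variance component rests on three levels; its
  per-gene estimate is noisy by construction and tPVE/sPVE are best read as
  rankings, not calibrated fractions.
- When the embedding separates conditions completely (strong `s` under
  HVG-style selection), group and cluster become confounded: tF picks up
  state signal and sPVE loses it. This is a property of the pipeline being
  studied, not of the estimator — the oracle selection does not suffer
  from it — but it limits how decisively score-based type-not-state
  selections can beat HVG at 3 + 3 replicate samples under realistic
  between-sample variance.
- The DSA engine is one cluster-based pseudobulk implementation;
  neighbourhood-based alternatives are out of scope, and `concordance`
  accepts externally produced p* tables for cross-method comparisons.
- Only the `G = 2` two-condition design is exercised end to end; the code
  accepts `G > 2` but reports the first non-reference contrast's log
  fold-change.
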