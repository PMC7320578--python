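# Methods

`skinpah` implements the statistical core of a two-city skin-microbiome /
pollution study design: community assembly testing against the Sloan
neutral model, cross-domain (bacteria + fungi) association networks with
attack-stability analysis, a PCA-based exposure index for hair PAH
(polycyclic aromatic hydrocarbon) measurements with dose-response
testing, and the supporting community statistics. Every analysis is
exercised against a synthetic cohort generator with planted, recoverable
structure. This note documents the models, the defaults and why they
were chosen, what the generator does and does not emulate, and the
numerical decisions.

## Sloan neutral model

A taxon's occurrence frequency across local communities is predicted
from its mean relative abundance `p` under neutral
birth-death-immigration dynamics. With local community size `N_t` (reads
per sample after rarefaction) and migration rate `m`, the stationary
local relative abundance is Beta(N_t m p, N_t m (1 - p)), and the
probability of detection above a relative-abundance threshold `d` is

    F(p) = 1 - I_d(N_t m p, N_t m (1 - p)),

`I_d` the regularized incomplete beta function. Choices:

- **Detection threshold** `d = 1/N_t` with `N_t` the mean
  post-rarefaction library size — one read at the average depth, the
  dominant convention in this literature. `N_t` is fixed, not
  co-estimated: only the product `N_t m` is identified by the occupancy
  curve.
- **Fitting** is one-dimensional least squares of `F(p_i)` against the
  observed occurrence frequencies, in untransformed frequency space,
  solved by bounded scalar minimisation on `m in (1e-6, 1]`
  (`xatol = 1e-10`). A dense grid search (step 1e-4) is kept as an
  independent oracle; the two agree to within one grid step on every
  benchmarked instance.
- **Null models**: binomial `1 - CDF_Binom(ceil(N_t d) - 1; N_t, p)` and
  Poisson `1 - CDF_Pois(ceil(N_t d) - 1; N_t p)` — random read sampling
  with no dynamics. Models are compared by Gaussian-residual AIC,
  `n ln(RSS/n) + 2(k+1)` with the residual variance counted as a
  parameter (`k = 1` for neutral, `0` for the nulls); all three are
  scored on the same residual scale. `RSS = 0` returns a `-inf`
  sentinel.
- **Classification** uses a Wilson score interval (level 0.95) around
  each predicted frequency, treated as a binomial proportion over the
  number of samples. Wilson rather than Clopper-Pearson because it is
  well-behaved near 0 and 1 and matches the implementation lineage this
  analysis style descends from.

The plug-in fit has a known small upward bias in `m` when counts (not
the latent frequencies) define detection: multinomial read sampling
smooths the detection step, so taxa just below `d` are sometimes seen
and the fitted curve compensates. On the benchmark conditions
(m = 0.1, N_t = 10,000, 300 taxa, 200 samples, depth 10,000) the median
fitted `m` is ≈ 0.116; the recovery tolerance of ±20% absorbs this.

## Cross-domain association networks

Counts are prevalence-filtered (taxa in ≥ 25% of samples kept; the
boundary is inclusive), CLR-transformed per domain with pseudocount 1,
column-standardised and concatenated. The graph is estimated by
Meinshausen-Bühlmann neighborhood selection: an L1-penalised regression
of each node on all others along a 20-point log-spaced penalty path from
the maximum absolute correlation down by 1e-2. The penalty is chosen by
stability selection (StARS): over 50 subsamples of size
`min(floor(10 sqrt n), floor(0.8 n))` drawn without replacement, edge
selection frequencies (OR rule over the two directed regressions) give
an average instability `2 theta (1 - theta)`; the statistic is
monotonised from the sparse end and the smallest penalty keeping it
≤ 0.05 is retained. The `10 sqrt n` subsample size is the canonical
StARS choice; larger overlapping subsamples underestimate instability
and select over-dense graphs (we measured chain-graph precision dropping
from ≈ 0.9 to ≈ 0.6 with 0.8 n subsamples). If no penalty qualifies the
densest path entry is returned with a warning.

Edge weights are the max-magnitude symmetrised regression coefficients
on standardised CLR data — a correlation-like strength — and edges with
|weight| ≤ 0.15 are then discarded (strict ≤, so a weight of exactly
0.15 is removed). Betweenness centrality and natural connectivity use
the unweighted 0/1 adjacency; signs and weights are kept for summaries
only.

**Natural connectivity** is `ln((1/n) sum_i exp(lambda_i))` over the
adjacency eigenvalues — the log-average closed-walk count. The eigen
route is checked against an explicit walk-sum oracle
(`sum_k tr(A^k)/k!`) exhaustively on all labelled graphs up to 6 nodes
and on random 7-8-node graphs, agreeing to < 1e-8.

**Attack curves** rank nodes once on the intact graph by betweenness
(ties: degree, then lexical id) and remove them in order without
re-ranking, recording natural connectivity after each removal and the
percent reduction versus the intact value. Single-ranking is exposed as
the only mode because re-ranking is a different experiment, not a
refinement.

## Exposure index and dose-response

Hair-PAH concentrations (pg/mg, one-year window) are log-transformed
(natural log; the base only rescales standardised columns), below-LOD
cells are substituted at LOD/2 by default (LOD itself selectable), and
each analyte column is standardised by default — correlation-matrix PCA,
so analytes with large dynamic range do not dominate. Standardisation
changes the PC1 explained-variance figure, so both modes are computed
and reported by the validation suite. The score is the projection on the
leading covariance eigenvector, oriented so that a higher score means
higher overall exposure (positive correlation with the mean standardised
log concentration). Subjects are split into `k = 8` rank-balanced groups
(sizes differing by ≤ 1, ties broken by stable input order; for n = 202
this gives six groups of 25 and two of 26). Dose-response uses
tie-corrected Spearman rank correlation with the t-approximation
p-value; constant inputs return NaN with a warning.

## Supporting statistics

- **Rarefaction**: multivariate hypergeometric subsampling to exactly
  the target depth (10,452 reads for 16S, 8,194 for ITS by default);
  shallower samples are dropped and logged. Expected rarefied counts
  equal depth × original proportions.
- **Diversity**: plug-in Shannon entropy (natural log). The plug-in
  estimator replaces richness-adjusted alternatives to keep the stage
  dependency-free; it is downward-biased at low depth but monotone
  comparisons across equally-rarefied samples are unaffected. Good's
  coverage is `1 - singletons/reads`.
- **Distances**: Bray-Curtis dissimilarity and binary Jaccard via
  `scipy.spatial.distance.pdist`. An all-zero sample pair has undefined
  dissimilarity and is set to 0 with a warning. Bray-Curtis violates the
  triangle inequality; no metric property beyond symmetry, zero
  diagonal and [0, 1] range is asserted.
- **PERMANOVA**: Gower-centred `-D²/2`, pseudo-F from among/within
  traces, p-value `(1 + #{F_perm >= F_obs})/(n_perm + 1)` under label
  permutation (999 by default). The statistic is verified against
  scikit-bio's implementation in the tests. Note that in perfectly
  balanced two-group designs the complete label swap reproduces F
  exactly, so the attainable minimum p is then `2/(n_perm + 1)` in
  expectation.
- **CSS normalisation**: per sample, the scaling factor is the sum of
  counts up to the chosen quantile of the sample's nonzero counts;
  normalised values are `count/s_j × 1000`. The adaptive percentile is
  the smallest grid value (0.25 to 1.0, step 0.05) at which the median
  scaling factor's successive relative change drops below 0.1 — the
  verbal "stabilisation" rule admits several formalisations; this one is
  simple, deterministic, and reduces to total-sum scaling at percentile
  1.0.
- **Associations**: arcsine-square-root transform of relative abundances
  (log of CSS values selectable), one OLS fit per feature on all
  covariates simultaneously (categorical covariates dummy-encoded,
  collinear columns dropped greedily by rank with a warning), BH
  adjustment across the full feature × covariate grid — conservative and
  deterministic — and a significance flag at q ≤ 0.25.

## Synthetic cohort generator

The generator emulates the study design, not the study data: 204
subjects split 102/102 across two cities, cheek and scalp samples per
subject, 300 bacterial and 150 fungal taxa, 20 analytes.

- **Exposures**: per-analyte log-normal concentrations (log-SD 0.8,
  baseline medians spanning ~20-600 pg/mg). Half the analytes act as
  parent PAHs whose city-A medians are multiplied by factors drawn
  uniformly from [1.5, 2.8]. Detection limits sit at the 5th percentile
  of each analyte's marginal, so ≈ 5% of cells are censored (flagged,
  value set to the LOD).
- **Neutral mode** samples Beta(N_t m p, N_t m (1-p)) local frequencies
  around a log-normal metacommunity (log-SD 1.0; see the Sloan section
  for why the spread matters to plug-in recovery), then multinomial
  reads — the same algebra the fitter assumes, so parameter recovery is
  a meaningful test.
- **Graph mode** builds a precision matrix from the planted signed edge
  list (off-diagonals ∓0.35, diagonal inflated if needed to keep the
  smallest eigenvalue above 0.05), draws multivariate-normal
  log-abundances, and emits per-domain multinomial counts from softmax
  compositions — a logistic-normal model whose conditional-independence
  structure is exactly the planted graph, which is what neighborhood
  selection targets.
- **Dose mode** shifts planted taxa's log-abundance by `effect × true
  exposure score` (the standardised mean of standardised log
  concentrations) before count sampling. Planted taxa get a baseline one
  log-unit above the community average, mirroring the fact that
  dose-responsive taxa of interest are major colonizers, not rare
  satellites.
- **Depths** are log-normal with median 1.5× the rarefaction target
  (log-SD 0.25), so a small tail of libraries falls below the target and
  rarefaction has real work to do.

What the generator does **not** emulate: phylogenetic structure,
taxonomy, within-subject longitudinal dynamics, contaminants, sequence
error, or the actual abundance distribution of skin communities.
Passing recovery tests therefore demonstrates correctness of the
estimators under their stated assumptions — not that real skin data meet
those assumptions.

## Benchmark problem sizes

The validation suite (`skinpah.evaluation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: 20 neutral
simulations at 300 taxa × 200 samples × depth 10,000; 10 chain-graph and
10 empty-graph network recoveries at 60 and 40 taxa × 300 and 200
samples; 500 PERMANOVA null simulations at 30 samples × 99 permutations;
50 dose-power and 50 null cohorts at the full 204-subject design; 50
null FDR simulations at 200 features × 100 samples; exhaustive
natural-connectivity checks on all graphs up to 6 nodes plus 200 random
7-8-node graphs. These sizes give stable Monte-Carlo medians while the
whole suite completes in a few minutes.

## Known limitations

- Only `N_t m` is identified by the occupancy curve; reported `m` values
  inherit any error in the fixed `N_t`.
- Network edge weights are regression coefficients, not correlations;
  the |0.15| filter is applied to them as the correlation-like strength,
  and absolute weights are not comparable across very different sample
  sizes.
- StARS instability is estimated from finite subsamples; very small
  cohorts (n < 25) make the selection noisy.
- The association stage is an ordinary linear model on transformed
  relative abundances — adequate for rank-level screening at q ≤ 0.25,
  not a count-model replacement.
- PC1 summarises correlated exposure profiles; it is not a toxicological
  equivalence weighting, and its explained variance depends on the
  standardisation convention (both are reported).
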