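# skinpah

Analysis toolkit for skin-microbiome surveys with pollution-exposure
biomonitoring: does a community assemble neutrally, how robust is its
cross-domain (bacteria–fungi) association network, and do taxa respond
dose-dependently to a subject's polycyclic aromatic hydrocarbon (PAH)
burden measured in hair?

It is written for microbiome researchers analysing paired 16S/ITS OTU
count tables with per-subject exposure chemistry, and ships a synthetic
cohort generator with planted ground truth so every stage can be
validated without sequence data.

## What it computes

**Sloan neutral model.** A taxon with mean relative abundance *p* is
detected (relative abundance ≥ *d*) in a fraction

&nbsp;&nbsp;&nbsp;&nbsp;*F(p) = 1 − I_d(N_t m p, N_t m (1 − p))*

of samples under neutral birth–death–immigration dynamics, with *N_t*
the local community size (reads/sample) and *m* the migration rate.
`fit_sloan` estimates *m* by least squares, reports *R²*, compares the
fit against binomial and Poisson sampling nulls by AIC, and classifies
each taxon as above / within / below the 95% Wilson band around its
prediction.

**Cross-domain networks.** Prevalence-filtered counts are CLR-
transformed per domain and a sparse conditional-dependence graph is
estimated by neighborhood selection (per-node L1 regressions) with
StARS stability selection of the penalty. Weak edges (|w| ≤ 0.15) are
discarded. Robustness is the natural connectivity
*ln((1/n) Σ e^{λ_i})* of the adjacency spectrum, tracked under
betweenness-ranked node removal.

**Exposure index.** Log-normalised analyte concentrations are collapsed
to the first principal component (oriented so higher = more exposed),
subjects are split into eight balanced groups, and features are tested
for monotone dose-response by Spearman rank correlation.

**Community statistics.** Rarefaction, plug-in Shannon diversity,
Good's coverage, Bray-Curtis / binary-Jaccard PERMANOVA, cumulative-sum
scaling (CSS), a 0.1% overall-abundance filter, and a covariate-
adjusted per-feature association stage with Benjamini-Hochberg control
at q ≤ 0.25.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

```python
from skinpah import (classify_taxa, fit_sloan, occupancy_abundance,
                     simulate_neutral_community)

table, truth = simulate_neutral_community(
    n_taxa=300, n_samples=200, N_t=10_000, m=0.1, depth=10_000, seed=42)
points = occupancy_abundance(table)
fit = classify_taxa(fit_sloan(points, N_t=float(table.library_sizes().mean())))
print(fit.m, fit.R2)
```

Running `python examples/neutral_assembly.py` (the same computation)
prints:

```
planted m          : 0.100
fitted  m          : 0.116
goodness of fit R^2: 0.969
AIC neutral / binomial / Poisson: -2363.4 / -1283.6 / -1283.6
taxa vs 95% band   : {'above': 0.34, 'within': 0.62, 'below': 0.04}
```

The fitted migration rate tracks the planted 0.1 (the small upward
offset is the read-sampling smoothing of the detection step, see the
methods note), the high *R²* and the AIC gap identify the community as
neutrally assembled, and most taxa sit inside the 95% prediction band.

Other capabilities, one script each, in `examples/`:
`cross_domain_network.py`, `exposure_dose_response.py`,
`community_statistics.py`, `full_pipeline.py`. For instance
`exposure_dose_response.py` builds the 204-subject cohort with one taxon
planted at +0.5 log-units per SD of exposure and prints

```
PC1 explained variance: 11.8%
group sizes           : [25, 25, 25, 25, 26, 26, 26, 26]
Spearman rho          : 0.496  (p = 4.29e-14)
```

— the planted dose-response is recovered as a strong positive rank
correlation.

A thin CLI mirrors the library:
`skinpah simulate|neutral|network|exposure|stats|run` (see
`skinpah --help`).

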