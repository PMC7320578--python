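"""Fit the Sloan neutral model to a simulated community and classify taxa.

Simulates a 300-taxon, 200-sample community with migration rate m = 0.1
and local community size N_t = 10,000, then refits the model from the
occupancy-abundance cloud and compares it against binomial and Poisson
sampling nulls.
"""

import numpy as np

from skinpah import (
    classify_taxa,
    fit_sloan,
    occupancy_abundance,
    simulate_neutral_community,
)

table, truth = simulate_neutral_community(
    n_taxa=300, n_samples=200, N_t=10_000, m=0.1, depth=10_000, seed=42
)
points = occupancy_abundance(table)
fit = classify_taxa(fit_sloan(points, N_t=float(table.library_sizes().mean())))

print(f"planted m          : {truth.m:.3f}")
print(f"fitted  m          : {fit.m:.3f}")
print(f"goodness of fit R^2: {fit.R2:.3f}")
print(
    "AIC neutral / binomial / Poisson: "
    f"{fit.aic_neutral:.1f} / {fit.aic_binomial:.1f} / {fit.aic_poisson:.1f}"
)
frac = {c: float(np.mean(fit.taxon_class == c)) for c in ("above", "within", "below")}
print(f"taxa vs 95% band   : {frac}")
print(
    "\nThe fitted migration rate tracks the planted one, the neutral model"
    "\nwins the AIC comparison, and most taxa sit inside the 95% band -"
    "\nthe signature of a neutrally assembled community."
)
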