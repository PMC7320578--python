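"""Supporting community statistics on a small simulated cohort.

Rarefies counts, computes Shannon diversity and Good's coverage, tests
city structure by PERMANOVA on Bray-Curtis distances, CSS-normalises the
table, and fits the covariate-adjusted association stage with BH FDR.
"""

import numpy as np

from skinpah import (
    CohortSpec,
    css_normalize,
    distance,
    fit_associations,
    goods_coverage,
    permanova,
    rarefy,
    shannon,
    simulate_cohort,
)

spec = CohortSpec(
    n_subjects=40, city_split=(20, 20), n_bacteria=60, n_fungi=30,
    n_analytes=10, depth_median_bacteria=4000, depth_median_fungi=3000, seed=3,
)
bundle, _ = simulate_cohort(spec)

rare = rarefy(bundle.bacteria, depth=2500, seed=1)
h = shannon(rare.counts.to_numpy())
cov = goods_coverage(rare.counts.to_numpy())
print(f"samples after rarefaction to 2500 reads: {rare.n_samples}")
print(f"Shannon diversity : median {np.median(h):.2f}")
print(f"Good's coverage   : min {cov.min():.3f} (sampling depth adequacy)")

D = distance(rare, "bray_curtis")
meta = bundle.meta.loc[rare.sample_ids]
res = permanova(D, meta["site"], n_perm=999, seed=0, grouping="site")
print(f"PERMANOVA site    : pseudo-F {res.pseudo_F:.2f}, p = {res.p:.4f}")

css = css_normalize(bundle.bacteria)
print(f"CSS-normalised matrix: {css.shape[0]} samples x {css.shape[1]} taxa")

cheek = bundle.meta.index[bundle.meta.site == "cheek"]
feats = bundle.bacteria.select_samples(cheek).relative_abundance()
covars = bundle.meta.loc[cheek, ["city", "age_group"]]
assoc = fit_associations(feats, covars, ["city", "age_group"], q_threshold=0.25)
print(
    f"association tests : {len(assoc)} feature x covariate fits, "
    f"{int(assoc.significant.sum())} flagged at q <= 0.25"
)
print(
    "\nSite separates communities strongly (small PERMANOVA p); with no"
    "\nplanted covariate effects, few or no associations should be flagged."
)
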