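"""Run every analysis stage end-to-end on a small synthetic cohort.

Writes diversity, PERMANOVA, exposure-index, dose-response, association,
network and neutral-model tables plus a reproducibility manifest to
``pipeline_output/``.
"""

from pathlib import Path

from skinpah import AnalysisConfig, CohortSpec, run_pipeline, simulate_cohort

spec = CohortSpec(
    n_subjects=24, city_split=(12, 12), n_bacteria=40, n_fungi=20,
    n_analytes=8, depth_median_bacteria=3000, depth_median_fungi=2500,
    planted_dose_taxa=[("OTU_B0001", 0.8)], seed=7,
)
bundle, _ = simulate_cohort(spec)

config = AnalysisConfig(
    rarefaction_depth_bacteria=1500,
    rarefaction_depth_fungi=1200,
    n_exposure_groups=4,
    n_permutations=99,
    n_subsamples=10,
    seed=3,
)
out = Path("pipeline_output")
results = run_pipeline(bundle, config, out)

print("stages run:", ", ".join(results["manifest"]["stages"]))
print("outputs:")
for f in sorted(out.iterdir()):
    print("  ", f.name)
print("\nneutral-model fits per (domain, city, site):")
print(results["neutral"][["domain", "city", "site", "m", "R2"]].to_string(index=False))
print(
    "\nEvery threshold and seed used is recorded in manifest.json;"
    "\nre-running with the same config reproduces all outputs exactly."
)
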