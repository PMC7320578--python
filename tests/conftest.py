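import numpy as np
import pandas as pd
import pytest

from skinpah import CohortSpec, TaxonTable, simulate_cohort


@pytest.fixture
def tiny_table() -> TaxonTable:
    counts = pd.DataFrame(
        [[1, 2], [3, 4], [5, 6]],
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
        columns=pd.Index(["OTU_B1", "OTU_F1"], name="taxon_id"),
    )
    domain = pd.Series(
        ["bacteria", "fungi"], index=counts.columns, name="domain"
    )
    return TaxonTable(counts, domain)


@pytest.fixture
def random_table() -> TaxonTable:
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(20, 50)),
        index=pd.Index([f"S{i}" for i in range(20)], name="sample_id"),
        columns=pd.Index([f"T{i}" for i in range(50)], name="taxon_id"),
    )
    domain = pd.Series(
        ["bacteria" if i < 30 else "fungi" for i in range(50)],
        index=counts.columns,
        name="domain",
    )
    genus = pd.Series(
        [f"genus{i % 7}" for i in range(50)], index=counts.columns, name="genus"
    )
    return TaxonTable(counts, domain, genus)


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down cohort for pipeline-level tests."""
    spec = CohortSpec(
        n_subjects=24,
        city_split=(12, 12),
        n_bacteria=40,
        n_fungi=20,
        n_analytes=8,
        depth_median_bacteria=3000,
        depth_median_fungi=2500,
        planted_dose_taxa=[("OTU_B0001", 0.8)],
        seed=7,
    )
    return simulate_cohort(spec)
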