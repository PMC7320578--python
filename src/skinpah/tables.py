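"""Tabular containers and TSV readers/writers for the pipeline.

The central observational unit is the :class:`TaxonTable`, an integer
sample-by-taxon count matrix with per-taxon domain (bacteria/fungi) and
genus annotations.  Per-sample metadata live in a plain pandas DataFrame
validated by :func:`read_sample_frame`; hair-PAH concentrations live in an
:class:`ExposureTable`.  On disk all tables are UTF-8 TSV with ``#``
comment lines; count tables are stored taxa-as-rows (the dominant amplicon
convention) and held in memory samples-by-taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    CohortAlignmentError,
    DuplicateIdError,
    EmptyTableError,
    InvalidCountError,
)

logger = logging.getLogger(__name__)

VALID_DOMAINS = ("bacteria", "fungi")
VALID_SITES = ("cheek", "scalp")
VALID_CITIES = ("A", "B")
VALID_PHENOTYPES = ("healthy", "acne", "dandruff")

#: header sentinel marking a samples-as-rows orientation on disk
SAMPLE_ROW_SENTINEL = "sample_id"
#: header marking BIOM-style sparse triplets
TRIPLET_COLUMNS = ("taxon_id", "sample_id", "count")


@dataclass
class TaxonTable:
    """Sample-by-taxon integer count matrix with taxon annotations.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are taxon ids, integer
        counts >= 0.
    domain
        Per-taxon label in ``{"bacteria", "fungi"}`` aligned to columns.
    genus
        Per-taxon free-text genus label (``"unclassified"`` allowed).
    """

    counts: pd.DataFrame
    domain: pd.Series
    genus: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.genus is None:
            self.genus = pd.Series(
                "unclassified", index=self.counts.columns, name="genus"
            )
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample id(s): {dups}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate taxon id(s): {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise InvalidCountError("counts must be numeric")
        if np.any(arr < 0):
            raise InvalidCountError("counts must be >= 0")
        if not np.allclose(arr, np.round(arr)):
            raise InvalidCountError("counts must be integers")
        self.counts = c.astype(np.int64)
        missing = self.counts.columns.difference(self.domain.index)
        if len(missing):
            raise InvalidCountError(f"taxa without domain label: {list(missing)[:5]}")
        self.domain = self.domain.reindex(self.counts.columns)
        bad = set(self.domain.unique()) - set(VALID_DOMAINS)
        if bad:
            raise InvalidCountError(f"invalid domain label(s): {bad}")
        self.genus = self.genus.reindex(self.counts.columns).fillna("unclassified")

    # -- convenience -----------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        lib = self.library_sizes().to_numpy()[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            ra = self.counts.to_numpy(dtype=float) / lib
        return pd.DataFrame(
            np.nan_to_num(ra), index=self.counts.index, columns=self.counts.columns
        )

    def select_samples(self, sample_ids) -> "TaxonTable":
        return TaxonTable(self.counts.loc[list(sample_ids)], self.domain, self.genus)

    def select_taxa(self, taxon_ids) -> "TaxonTable":
        ids = list(taxon_ids)
        return TaxonTable(self.counts[ids], self.domain[ids], self.genus[ids])


def read_taxon_table(
    path: str | Path,
    domain_map: Mapping[str, str] | str | Path | None = None,
    genus_map: Mapping[str, str] | None = None,
) -> TaxonTable:
    """Read a count table from TSV (dense or BIOM-style sparse triplets).

    Dense files are taxa-as-rows (first column taxon id) unless the first
    header field is ``sample_id``, in which case rows are samples.  Taxa
    absent from *domain_map* are labelled ``bacteria`` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.startswith("#") or line.rstrip("\n").split("\t")[:1] == [
                "#OTU ID"
            ]:
                header = line.rstrip("\n").split("\t")
                break
    if header is None:
        raise EmptyTableError(f"no data rows in {path}")
    if len(set(header)) != len(header):
        dups = sorted({c for c in header if header.count(c) > 1})
        raise DuplicateIdError(f"duplicate column id(s): {dups}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise EmptyTableError(f"no data rows in {path}")
    if tuple(df.columns[:3]) == TRIPLET_COLUMNS:
        dup = df.duplicated(subset=["taxon_id", "sample_id"])
        if dup.any():
            raise DuplicateIdError("duplicate (taxon, sample) triplet entries")
        wide = (
            df.assign(count=pd.to_numeric(df["count"], errors="coerce"))
            .pivot(index="sample_id", columns="taxon_id", values="count")
            .fillna(0)
        )
        counts = wide
    else:
        first = df.columns[0]
        body = df.set_index(first)
        if body.index.duplicated().any():
            dups = body.index[body.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate row id(s): {dups}")
        num = body.apply(pd.to_numeric, errors="coerce")
        if num.isna().any().any():
            bad = num.columns[num.isna().any()].tolist()
            raise InvalidCountError(f"non-numeric counts in column(s) {bad[:5]}")
        counts = num if first == SAMPLE_ROW_SENTINEL else num.T
    counts.index.name = "sample_id"
    counts.columns.name = "taxon_id"

    if isinstance(domain_map, (str, Path)):
        dm = pd.read_csv(domain_map, sep="\t", comment="#", index_col=0)
        genus_map = dm["genus"].to_dict() if "genus" in dm else genus_map
        domain_map = dm.iloc[:, 0].to_dict()
    domain_map = dict(domain_map or {})
    missing = [t for t in counts.columns if t not in domain_map]
    if missing:
        logger.warning(
            "%d taxa absent from domain map; labelled 'bacteria'", len(missing)
        )
    domain = pd.Series(
        [domain_map.get(t, "bacteria") for t in counts.columns],
        index=counts.columns,
        name="domain",
    )
    genus = (
        pd.Series(
            [dict(genus_map).get(t, "unclassified") for t in counts.columns],
            index=counts.columns,
            name="genus",
        )
        if genus_map
        else None
    )
    return TaxonTable(counts, domain, genus)


def write_taxon_table(
    table: TaxonTable, path: str | Path, taxonomy_path: str | Path | None = None
) -> None:
    """Write counts taxa-as-rows; optionally a taxonomy sidecar TSV."""
    out = table.counts.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")
    if taxonomy_path is not None:
        tax = pd.DataFrame({"domain": table.domain, "genus": table.genus})
        tax.index.name = "taxon_id"
        tax.to_csv(taxonomy_path, sep="\t")


# -- sample metadata -----------------------------------------------------

def validate_sample_frame(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-sample metadata frame (subject, city, site, ...)."""
    required = {"sample_id", "subject_id", "city", "site", "phenotype"}
    missing = required - set(meta.columns)
    if missing:
        raise InvalidCountError(f"metadata missing column(s): {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise DuplicateIdError("duplicate sample_id in metadata")
    if meta.duplicated(subset=["subject_id", "site"]).any():
        raise DuplicateIdError("a subject has more than one sample per site")
    bad_site = set(meta["site"]) - set(VALID_SITES)
    if bad_site:
        raise InvalidCountError(f"invalid site label(s): {bad_site}")
    bad_ph = set(meta["phenotype"]) - set(VALID_PHENOTYPES)
    if bad_ph:
        raise InvalidCountError(f"invalid phenotype label(s): {bad_ph}")
    acne_off = meta[(meta["phenotype"] == "acne") & (meta["site"] != "cheek")]
    dand_off = meta[(meta["phenotype"] == "dandruff") & (meta["site"] != "scalp")]
    if len(acne_off) or len(dand_off):
        raise InvalidCountError(
            "acne is a cheek phenotype and dandruff a scalp phenotype"
        )
    return meta.set_index("sample_id", drop=False)


def read_sample_frame(path: str | Path) -> pd.DataFrame:
    return validate_sample_frame(pd.read_csv(path, sep="\t", comment="#"))


def write_sample_frame(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# -- exposures -----------------------------------------------------------

@dataclass
class ExposureTable:
    """Subject-by-analyte PAH concentrations (pg/mg hair) with LOD flags."""

    concentrations: pd.DataFrame
    below_lod: pd.DataFrame
    lod: pd.Series

    def __post_init__(self) -> None:
        c = self.concentrations
        if c.index.duplicated().any():
            raise DuplicateIdError("duplicate subject id in exposure table")
        if (c.to_numpy() < 0).any():
            raise InvalidCountError("concentrations must be >= 0")
        self.below_lod = self.below_lod.reindex(
            index=c.index, columns=c.columns
        ).fillna(False).astype(bool)
        self.lod = self.lod.reindex(c.columns).fillna(0.0)

    @property
    def subject_ids(self) -> pd.Index:
        return self.concentrations.index

    @property
    def analyte_ids(self) -> pd.Index:
        return self.concentrations.columns

    def select_subjects(self, subject_ids) -> "ExposureTable":
        ids = list(subject_ids)
        return ExposureTable(
            self.concentrations.loc[ids], self.below_lod.loc[ids], self.lod
        )


def read_exposure_table(path: str | Path) -> ExposureTable:
    """Read concentrations; below-LOD cells are marked with a ``<`` prefix.

    A comment line ``# lod: analyte=value ...`` carries per-analyte limits.
    """
    path = Path(path)
    lod: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# lod:"):
                for tok in line.split(":", 1)[1].split():
                    k, v = tok.split("=")
                    lod[k] = float(v)
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    below = raw.apply(lambda col: col.str.startswith("<"))
    conc = raw.apply(lambda col: pd.to_numeric(col.str.lstrip("<")))
    return ExposureTable(conc, below, pd.Series(lod, dtype=float))


def write_exposure_table(expo: ExposureTable, path: str | Path) -> None:
    out = expo.concentrations.astype(object).copy()
    mask = expo.below_lod.to_numpy()
    vals = expo.concentrations.to_numpy()
    for i, j in zip(*np.nonzero(mask)):
        out.iat[i, j] = f"<{vals[i, j]:g}"
    with open(path, "w") as fh:
        fh.write(
            "# lod: "
            + " ".join(f"{k}={v:g}" for k, v in expo.lod.items())
            + "\n"
        )
        out.index.name = "subject_id"
        out.to_csv(fh, sep="\t")


# -- cohort alignment ----------------------------------------------------

@dataclass
class CohortBundle:
    """Sample-aligned bacteria/fungi tables, metadata and exposures."""

    bacteria: TaxonTable
    fungi: TaxonTable
    meta: pd.DataFrame
    exposures: ExposureTable
    dropped: dict = field(default_factory=dict)


def validate_cohort(
    table_b: TaxonTable,
    table_f: TaxonTable,
    meta: pd.DataFrame,
    expo: ExposureTable,
) -> CohortBundle:
    """Intersect the four inputs on shared ids and align sample order.

    Samples are kept when present in both domain tables and the metadata
    and when their subject has exposure data; retained samples are ordered
    by sorted sample id so the result is invariant to input row order.
    The returned bundle's ``dropped`` dict reports what was removed.
    """
    meta = validate_sample_frame(meta.reset_index(drop=True))
    subjects = meta["subject_id"].unique()
    shared_subj = sorted(set(subjects) & set(expo.subject_ids))
    samples = (
        set(table_b.sample_ids) & set(table_f.sample_ids) & set(meta["sample_id"])
    )
    keep = sorted(
        s for s in samples if meta.loc[s, "subject_id"] in set(shared_subj)
    )
    if not keep:
        raise CohortAlignmentError("no samples shared across all inputs")
    dropped = {
        "subjects_without_exposure": sorted(set(subjects) - set(shared_subj)),
        "subjects_without_samples": sorted(
            set(expo.subject_ids) - set(subjects)
        ),
        "samples_dropped": sorted(
            (set(table_b.sample_ids) | set(table_f.sample_ids) | set(meta["sample_id"]))
            - set(keep)
        ),
    }
    logger.info(
        "cohort aligned: %d samples retained, %d subjects dropped",
        len(keep),
        len(dropped["subjects_without_exposure"]),
    )
    kept_subjects = sorted({meta.loc[s, "subject_id"] for s in keep})
    return CohortBundle(
        bacteria=table_b.select_samples(keep),
        fungi=table_f.select_samples(keep),
        meta=meta.loc[keep],
        exposures=expo.select_subjects(kept_subjects),
        dropped=dropped,
    )
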