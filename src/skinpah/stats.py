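"""Supporting community statistics: rarefaction, diversity, coverage,
beta-diversity with permutation tests, CSS normalisation, abundance
filtering, and a covariate-adjusted per-feature association stage with
Benjamini-Hochberg control at q <= 0.25.

These are the standard steps wrapped around the core analyses: counts are
rarefied to a common depth before diversity and neutral-model work,
between-sample structure is tested by PERMANOVA on Bray-Curtis or binary
Jaccard distances, and per-taxon associations with exposure and host
covariates are fitted by ordinary least squares on variance-stabilised
relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .errors import EmptyTableError
from .tables import TaxonTable

logger = logging.getLogger(__name__)


# -- rarefaction ---------------------------------------------------------

def rarefy(table: TaxonTable, depth: int, seed: int = 0) -> TaxonTable:
    """Subsample each library without replacement to exactly ``depth``.

    Samples with fewer reads than ``depth`` are dropped (logged).  The
    draw is multivariate hypergeometric, so expected post-rarefaction
    counts equal ``depth`` times the original proportions.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    lib = table.library_sizes()
    keep = lib.index[lib >= depth]
    if len(keep) == 0:
        raise EmptyTableError(f"no library reaches depth {depth}")
    if len(keep) < table.n_samples:
        logger.info(
            "rarefaction to %d dropped %d sample(s)",
            depth,
            table.n_samples - len(keep),
        )
    rng = np.random.default_rng(seed)
    sub = table.select_samples(keep)
    rows = [
        rng.multivariate_hypergeometric(row, depth)
        for row in sub.counts.to_numpy()
    ]
    counts = pd.DataFrame(rows, index=sub.sample_ids, columns=sub.taxon_ids)
    return TaxonTable(counts, sub.domain, sub.genus)


# -- alpha diversity -----------------------------------------------------

def shannon(counts) -> np.ndarray | float:
    """Plug-in Shannon entropy H = -sum p ln p per sample (natural log)."""
    arr = np.atleast_2d(np.asarray(counts, dtype=float))
    tot = arr.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("library size must be > 0")
    p = arr / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    return float(h[0]) if np.ndim(counts) == 1 else h


def goods_coverage(counts) -> np.ndarray | float:
    """Good's coverage 1 - singletons/reads per sample."""
    arr = np.atleast_2d(np.asarray(counts))
    tot = arr.sum(axis=1)
    if np.any(tot <= 0):
        raise ValueError("library size must be > 0")
    singletons = (arr == 1).sum(axis=1)
    cov = 1.0 - singletons / tot
    return float(cov[0]) if np.ndim(counts) == 1 else cov


# -- filtering and normalisation -----------------------------------------

def abundance_filter(table: TaxonTable, min_rel: float = 0.001) -> TaxonTable:
    """Drop taxa whose overall relative abundance is below ``min_rel``.

    Overall abundance is taxon total over grand total; the boundary is
    inclusive (exactly 0.1% is retained under the default).
    """
    tot = table.counts.to_numpy().sum()
    if tot == 0:
        raise EmptyTableError("table has no reads")
    rel = table.counts.sum(axis=0) / tot
    keep = table.taxon_ids[(rel >= min_rel).to_numpy()]
    logger.info(
        "abundance filter %.4g: %d -> %d taxa", min_rel, table.n_taxa, len(keep)
    )
    return table.select_taxa(keep)


def css_normalize(
    table: TaxonTable,
    percentile: float | None = None,
    scale: float = 1000.0,
) -> pd.DataFrame:
    """Cumulative-sum scaling: counts over the per-sample partial sum.

    For sample j and quantile l, the scaling factor ``s_j(l)`` is the sum
    of counts no larger than the l-quantile of the sample's nonzero
    counts.  With ``percentile=None`` the quantile is chosen adaptively as
    the smallest grid value at which the median scaling factor across
    samples stabilises (successive relative change below 0.1); a fixed
    percentile of 1.0 reduces to total-sum scaling.  Normalised values
    are ``count / s_j * scale``; samples with ``s_j = 0`` are dropped.
    """
    arr = table.counts.to_numpy(dtype=float)

    def factors(l: float) -> np.ndarray:
        s = np.zeros(arr.shape[0])
        for j, row in enumerate(arr):
            nz = row[row > 0]
            if len(nz) == 0:
                continue
            q = np.quantile(nz, l)
            s[j] = row[row <= q].sum()
        return s

    if percentile is None:
        grid = np.arange(0.25, 1.0001, 0.05)
        med = np.array([np.median(factors(l)) for l in grid])
        percentile = float(grid[-1])
        for i in range(len(grid) - 1):
            if med[i] > 0 and abs(med[i + 1] - med[i]) / med[i] < 0.1:
                percentile = float(grid[i])
                break
        logger.info("CSS adaptive percentile: %.2f", percentile)
    s = factors(float(percentile))
    ok = s > 0
    if not ok.all():
        logger.warning("dropping %d sample(s) with zero CSS factor", (~ok).sum())
    norm = arr[ok] / s[ok, None] * scale
    return pd.DataFrame(
        norm, index=table.sample_ids[ok], columns=table.taxon_ids
    )


# -- beta diversity ------------------------------------------------------

@dataclass
class DistanceMatrix:
    sample_ids: pd.Index
    matrix: np.ndarray  # full symmetric form
    metric: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)


def distance(data, metric: str = "bray_curtis") -> DistanceMatrix:
    """Bray-Curtis dissimilarity or binary Jaccard distance between samples.

    ``data`` is a TaxonTable or a samples-by-taxa DataFrame/array.  A pair
    of all-zero samples has undefined dissimilarity; it is set to 0 with
    a warning.
    """
    if isinstance(data, TaxonTable):
        df = data.counts
    else:
        df = pd.DataFrame(data)
    if df.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    X = df.to_numpy(dtype=float)
    if metric == "bray_curtis":
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = pdist(X, metric="braycurtis")
    elif metric == "binary_jaccard":
        cond = pdist(X > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if np.isnan(cond).any():
        logger.warning("all-zero sample pair(s): distance set to 0")
        cond = np.nan_to_num(cond)
    return DistanceMatrix(df.index, squareform(cond), metric)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    n_permutations: int
    grouping: str


def _pseudo_f(G: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from a Gower-centered matrix and integer group labels."""
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    a = len(groups)
    H = np.zeros((n, n))
    for g, c in zip(groups, counts):
        idx = np.nonzero(labels == g)[0]
        H[np.ix_(idx, idx)] = 1.0 / c
    ss_total = np.trace(G)
    ss_among = float(np.sum(H * G))  # trace(H G) since H symmetric idempotent
    ss_within = ss_total - ss_among
    if ss_within <= 0:
        return np.inf
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    D: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    grouping: str = "group",
) -> PermanovaResult:
    """Distance-based PERMANOVA with label-permutation p-value.

    Gower-centers -D^2/2 and forms the among/within pseudo-F; the p-value
    is ``(1 + #{F_perm >= F_obs}) / (n_perm + 1)``.
    """
    labels = np.asarray(pd.factorize(np.asarray(labels))[0])
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    Dm = D.matrix if isinstance(D, DistanceMatrix) else np.asarray(D)
    n = Dm.shape[0]
    A = -0.5 * Dm**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    f_obs = _pseudo_f(G, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _pseudo_f(G, rng.permutation(labels)) >= f_obs:
            hits += 1
    return PermanovaResult(
        pseudo_F=float(f_obs),
        p=(1 + hits) / (n_perm + 1),
        n_permutations=n_perm,
        grouping=grouping,
    )


# -- covariate-adjusted associations -------------------------------------

@dataclass
class AssociationResult:
    feature_id: str
    covariate: str
    coefficient: float
    standard_error: float
    p: float
    q: float = np.nan
    significant: bool = False


def _design_matrix(meta: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        s = meta[cov]
        if s.dtype.kind in "biufc":
            cols[cov] = s.astype(float)
        else:
            dummies = pd.get_dummies(s, prefix=cov, drop_first=True, dtype=float)
            for c in dummies:
                cols[c] = dummies[c]
    X = pd.DataFrame(cols, index=meta.index)
    X.insert(0, "intercept", 1.0)
    # drop collinear columns by greedy rank check
    keep, mat = ["intercept"], X[["intercept"]].to_numpy()
    for c in X.columns[1:]:
        cand = np.hstack([mat, X[[c]].to_numpy()])
        if np.linalg.matrix_rank(cand) > mat.shape[1]:
            keep.append(c)
            mat = cand
        else:
            logger.warning("dropping collinear covariate column %r", c)
    return X[keep]


def fit_associations(
    features: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: list[str],
    q_threshold: float = 0.25,
    transform: str = "arcsin_sqrt",
) -> pd.DataFrame:
    """Per-feature OLS on all covariates with BH control across the grid.

    ``features`` holds per-sample relative abundances (or CSS-normalised
    values with ``transform='log'``); the default variance-stabilising
    transform is arcsine-square-root.  All feature-by-covariate p-values
    are BH-adjusted together; flags mark q <= ``q_threshold``.
    """
    if not features.index.equals(meta.index):
        meta = meta.loc[features.index]
    Y = features.to_numpy(dtype=float)
    if transform == "arcsin_sqrt":
        Y = np.arcsin(np.sqrt(np.clip(Y, 0, 1)))
    elif transform == "log":
        Y = np.log(Y + 1.0)
    elif transform is not None and transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    X = _design_matrix(meta, covariates)
    Xm = X.to_numpy()
    n, k = Xm.shape
    if n <= k:
        raise ValueError("more covariates than samples")
    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    beta = XtX_inv @ Xm.T @ Y  # (k, n_features)
    resid = Y - Xm @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * sps.t.sf(np.abs(tvals), dof)

    rows = []
    for fi, feat in enumerate(features.columns):
        for ci, cov in enumerate(X.columns):
            if cov == "intercept":
                continue
            rows.append(
                {
                    "feature_id": feat,
                    "covariate": cov,
                    "coefficient": beta[ci, fi],
                    "standard_error": se[ci, fi],
                    "p": pvals[ci, fi],
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        rej, q, _, _ = multipletests(
            out["p"].fillna(1.0), alpha=q_threshold, method="fdr_bh"
        )
        out["q"] = q
        out["significant"] = out["q"] <= q_threshold
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (statsmodels step-up)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# -- thin two-group / k-group utilities ----------------------------------

def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (exact null for small samples)."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test across three or more groups."""
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
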