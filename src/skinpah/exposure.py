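"""PCA-based PAH exposure index, balanced grouping and dose-response.

A subject's year-averaged exposure is summarised by the first principal
component of the log-transformed (and by default column-standardised)
analyte matrix, oriented so that a higher score means higher overall
exposure.  Subjects are then split into ``k`` rank-balanced groups
(group 1 = lowest exposure) and microbiome features are tested for a
monotone dose-response against the score or group by Spearman rank
correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ExposureTable

logger = logging.getLogger(__name__)


@dataclass
class ExposureScore:
    """Per-subject PC1 pollution score and balanced exposure group."""

    score: pd.Series  # indexed by subject
    explained_variance: float  # fraction of total variance on PC1
    loadings: pd.Series  # per-analyte weights
    group: pd.Series | None = None  # 1..k, 1 = lowest exposure


def log_normalize(
    expo: ExposureTable,
    lod_policy: str = "half_lod",
    standardize: bool = True,
) -> pd.DataFrame:
    """Log-transform concentrations; below-LOD cells substituted first.

    ``lod_policy``: ``half_lod`` (default) replaces censored cells with
    LOD/2; ``lod`` uses the LOD itself.  With ``standardize`` each analyte
    column is centred to mean 0 and scaled to unit (sample) variance;
    zero-variance analytes are dropped with a warning.
    """
    conc = expo.concentrations.astype(float).copy()
    lod = expo.lod.reindex(conc.columns).fillna(0.0)
    sub = lod / 2.0 if lod_policy == "half_lod" else lod
    mask = expo.below_lod.to_numpy()
    vals = np.where(mask, np.broadcast_to(sub.to_numpy(), conc.shape), conc.to_numpy())
    if np.any(vals <= 0):
        raise ValueError("non-positive concentration after LOD substitution")
    logged = pd.DataFrame(np.log(vals), index=conc.index, columns=conc.columns)
    sd = logged.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning(
            "dropping zero-variance analyte(s): %s", list(sd.index[~keep])
        )
    logged = logged.loc[:, keep]
    if standardize:
        logged = (logged - logged.mean(axis=0)) / sd[keep]
    return logged


def pc1_score(matrix: pd.DataFrame) -> ExposureScore:
    """Project subjects on the leading eigenvector of the covariance.

    The sign is fixed so the score correlates positively with the mean
    standardised log concentration (higher score = higher exposure).
    Explained variance is lambda_1 / sum(lambda).
    """
    X = matrix.to_numpy(dtype=float)
    n, k = X.shape
    if n < 2 or k < 1:
        raise ValueError("need >= 2 subjects and >= 1 analyte")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    lam, vec = np.linalg.eigh(cov)
    lead = vec[:, -1]
    total = lam.sum()
    ev = float(lam[-1] / total) if total > 0 else 1.0
    score = Xc @ lead
    # orient: higher score = higher overall exposure
    overall = ((X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1)).mean(
        axis=1
    )
    if np.corrcoef(score, overall)[0, 1] < 0:
        score, lead = -score, -lead
    return ExposureScore(
        score=pd.Series(score, index=matrix.index, name="pc1_score"),
        explained_variance=ev,
        loadings=pd.Series(lead, index=matrix.columns, name="loading"),
    )


def balanced_groups(scores: pd.Series, k: int = 8) -> pd.Series:
    """Rank-based split into ``k`` contiguous groups, sizes differing <= 1.

    Ties are broken by stable input order; group 1 holds the lowest
    scores.  Invariant under any monotone relabelling of the scores.
    """
    n = len(scores)
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got {n}")
    order = np.argsort(scores.to_numpy(), kind="stable")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1  # earlier groups absorb the remainder
    labels = np.empty(n, dtype=int)
    start = 0
    for g, s in enumerate(sizes, start=1):
        labels[order[start : start + s]] = g
        start += s
    return pd.Series(labels, index=scores.index, name="exposure_group")


def score_exposures(
    expo: ExposureTable,
    k: int = 8,
    lod_policy: str = "half_lod",
    standardize: bool = True,
) -> ExposureScore:
    """log-normalise -> PC1 -> balanced groups, in one call."""
    es = pc1_score(log_normalize(expo, lod_policy, standardize))
    es.group = balanced_groups(es.score, k)
    return es


def spearman_dose_response(feature, exposure) -> tuple[float, float]:
    """Tie-corrected Spearman rho with t-approximation p-value.

    ``feature`` is a per-sample abundance or diversity value; ``exposure``
    the matching pollution score or group label (1-8).  Constant input is
    flagged by returning (nan, nan).
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(exposure, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need paired inputs of length >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input: Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
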