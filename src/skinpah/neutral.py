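"""Sloan neutral community model: occupancy-abundance fitting and nulls.

The neutral model predicts a taxon's occurrence frequency across local
communities from its mean relative abundance ``p`` in the metacommunity,
assuming neutral birth-death-immigration dynamics.  With local community
size ``N_t`` (reads per sample after rarefaction) and migration rate ``m``
(the probability that a death in the local community is replaced by an
immigrant rather than local reproduction), the stationary local relative
abundance of a taxon is Beta-distributed, and the probability of detecting
it above a relative-abundance threshold ``d`` is

    F(p) = 1 - I_d(N_t m p, N_t m (1 - p))

where ``I_d`` is the regularized incomplete beta function.  ``m`` is
estimated by nonlinear least squares of F(p_i) against the observed
occurrence frequencies; goodness of fit is the ordinary R².  Binomial and
Poisson occupancy nulls (random sampling with no dynamics) are compared to
the neutral fit via Gaussian-residual AIC, and each taxon is classified as
above / within / below a 95% Wilson band around its predicted frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EmptyTableError, FitError
from .tables import TaxonTable


@dataclass
class OccupancyPoints:
    """Per-taxon mean relative abundance and occurrence frequency."""

    taxon_id: np.ndarray
    p: np.ndarray  # mean relative abundance, 0-1
    f_obs: np.ndarray  # fraction of samples with rel. abundance >= d
    d: float  # detection threshold (relative abundance)
    n_samples: int

    def __len__(self) -> int:
        return len(self.p)


@dataclass
class NeutralFit:
    """Fitted migration rate with model comparison and taxon classes."""

    m: float
    N_t: float
    R2: float
    rss_neutral: float
    rss_binomial: float
    rss_poisson: float
    aic_neutral: float
    aic_binomial: float
    aic_poisson: float
    points: OccupancyPoints
    predicted: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    taxon_class: np.ndarray | None = None


def occupancy_abundance(
    table: TaxonTable, d: float | None = None
) -> OccupancyPoints:
    """Compute per-taxon (p, f_obs) occupancy-abundance points.

    ``p`` is the relative abundance averaged over samples; ``f_obs`` the
    share of samples where the taxon's relative abundance is >= ``d``.
    Default ``d = 1 / N_t`` with ``N_t`` the mean library size, i.e. one
    read at the average depth.  All-zero taxa are dropped.
    """
    if table.n_samples == 0 or table.n_taxa == 0:
        raise EmptyTableError("empty taxon table")
    ra = table.relative_abundance().to_numpy()
    if d is None:
        d = 1.0 / float(table.library_sizes().mean())
    p = ra.mean(axis=0)
    keep = p > 0
    f_obs = (ra[:, keep] >= d).mean(axis=0)
    return OccupancyPoints(
        taxon_id=np.asarray(table.taxon_ids)[keep],
        p=p[keep],
        f_obs=f_obs,
        d=float(d),
        n_samples=table.n_samples,
    )


def neutral_frequency(p, N_t: float, m: float, d: float):
    """Neutral predicted detection frequency F(p) = 1 - I_d(Nmp, Nm(1-p))."""
    p = np.asarray(p, dtype=float)
    a = N_t * m * p
    b = N_t * m * (1.0 - p)
    out = np.zeros_like(p)
    ok = (a > 0) & (b > 0)
    out[ok] = stats.beta.sf(d, a[ok], b[ok])
    out[p >= 1.0] = 1.0
    return out


def predict_null(model: str, p, N_t: float, d: float):
    """Binomial / Poisson occupancy nulls at detection threshold ``d``.

    Detection requires at least ``ceil(N_t * d)`` reads out of ``N_t``;
    with the default ``d = 1/N_t`` these reduce to ``1 - (1-p)^N_t`` and
    ``1 - exp(-N_t p)``.
    """
    p = np.asarray(p, dtype=float)
    k = int(np.ceil(N_t * d)) - 1
    if model == "binomial":
        return stats.binom.sf(k, int(round(N_t)), p)
    if model == "poisson":
        return stats.poisson.sf(k, N_t * p)
    raise ValueError(f"unknown null model {model!r}")


def _rss(f_pred: np.ndarray, f_obs: np.ndarray) -> float:
    return float(np.sum((f_obs - f_pred) ** 2))


def fit_sloan(points: OccupancyPoints, N_t: float) -> NeutralFit:
    """Estimate ``m`` by least squares and compare against the nulls.

    Raises :class:`FitError` if the bounded optimiser fails; bounds are
    m in (1e-6, 1], start at the bounded-Brent interior optimum.
    """
    if len(points) < 10:
        raise FitError(f"need >= 10 occupancy points, got {len(points)}")
    if N_t <= 0:
        raise FitError("N_t must be positive")
    p, f_obs, d = points.p, points.f_obs, points.d

    def rss_of(m: float) -> float:
        return _rss(neutral_frequency(p, N_t, m, d), f_obs)

    res = optimize.minimize_scalar(
        rss_of, bounds=(1e-6, 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise FitError(
            f"Sloan m fit failed (bounds (1e-6, 1], start bounded-Brent): "
            f"{res.message}"
        )
    m_hat = float(res.x)
    pred = neutral_frequency(p, N_t, m_hat, d)
    rss_n = _rss(pred, f_obs)
    tss = float(np.sum((f_obs - f_obs.mean()) ** 2))
    r2 = 1.0 - rss_n / tss if tss > 0 else 1.0
    rss_b = _rss(predict_null("binomial", p, N_t, d), f_obs)
    rss_p = _rss(predict_null("poisson", p, N_t, d), f_obs)
    n = len(points)
    return NeutralFit(
        m=m_hat,
        N_t=float(N_t),
        R2=r2,
        rss_neutral=rss_n,
        rss_binomial=rss_b,
        rss_poisson=rss_p,
        aic_neutral=model_aic(rss_n, k=1, n=n),
        aic_binomial=model_aic(rss_b, k=0, n=n),
        aic_poisson=model_aic(rss_p, k=0, n=n),
        points=points,
        predicted=pred,
    )


def grid_search_m(points: OccupancyPoints, N_t: float, step: float = 1e-4):
    """Dense grid search over m in (0, 1]; independent check of the NLS fit.

    Returns ``(m_grid_best, rss_at_best)``.  Evaluated in chunks to bound
    memory at ~p * chunk doubles.
    """
    grid = np.arange(step, 1.0 + step / 2, step)
    p, f_obs, d = points.p, points.f_obs, points.d
    best_m, best_rss = grid[0], np.inf
    for start in range(0, len(grid), 500):
        ms = grid[start : start + 500]
        a = N_t * ms[:, None] * p[None, :]
        b = N_t * ms[:, None] * (1.0 - p[None, :])
        pred = stats.beta.sf(d, a, b)
        rss = np.sum((pred - f_obs[None, :]) ** 2, axis=1)
        i = int(np.argmin(rss))
        if rss[i] < best_rss:
            best_rss, best_m = float(rss[i]), float(ms[i])
    return best_m, best_rss


def model_aic(rss: float, k: int, n: int) -> float:
    """Gaussian-residual AIC = n ln(RSS/n) + 2(k+1) (variance counted)."""
    if n <= k + 1:
        raise ValueError("need n > k + 1 points")
    if rss <= 0:
        return -np.inf
    return n * np.log(rss / n) + 2 * (k + 1)


def wilson_interval(p_hat, n: int, level: float = 0.95):
    """Wilson score interval for a binomial proportion (vectorised)."""
    p_hat = np.asarray(p_hat, dtype=float)
    z = stats.norm.ppf(0.5 + level / 2)
    denom = 1.0 + z * z / n
    center = (p_hat + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p_hat * (1 - p_hat) / n + z * z / (4 * n * n))
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


def classify_taxa(fit: NeutralFit, level: float = 0.95) -> NeutralFit:
    """Classify each taxon against the Wilson band around its prediction.

    The predicted frequency is treated as a binomial proportion observed
    over ``n_samples`` samples; taxa with f_obs above the upper bound are
    'above' (more prevalent than neutrality predicts), below the lower
    bound 'below', else 'within'.  Updates and returns ``fit``.
    """
    lo, hi = wilson_interval(fit.predicted, fit.points.n_samples, level)
    cls = np.where(
        fit.points.f_obs > hi, "above", np.where(fit.points.f_obs < lo, "below", "within")
    )
    fit.ci_low, fit.ci_high, fit.taxon_class = lo, hi, cls
    return fit


def genus_class_proportions(fit: NeutralFit, genus: pd.Series) -> pd.DataFrame:
    """Per-genus proportion of taxa above / within / below the band."""
    if fit.taxon_class is None:
        raise ValueError("call classify_taxa first")
    df = pd.DataFrame(
        {
            "genus": genus.reindex(fit.points.taxon_id).to_numpy(),
            "cls": fit.taxon_class,
        }
    )
    tab = pd.crosstab(df["genus"], df["cls"], normalize="index")
    for c in ("above", "within", "below"):
        if c not in tab:
            tab[c] = 0.0
    return tab[["above", "within", "below"]]


def fit_summary(fit: NeutralFit) -> pd.DataFrame:
    """Per-taxon table: p, f_obs, prediction, band and class."""
    return pd.DataFrame(
        {
            "taxon_id": fit.points.taxon_id,
            "mean_relative_abundance": fit.points.p,
            "occurrence_frequency": fit.points.f_obs,
            "predicted_frequency": fit.predicted,
            "ci_low": fit.ci_low,
            "ci_high": fit.ci_high,
            "neutral_class": fit.taxon_class,
        }
    )
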