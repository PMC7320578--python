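"""Self-validation benchmarks: estimator-on-generator recovery studies.

Each function simulates data with the synthetic generator under planted,
known structure, runs the corresponding analysis stage, and reports how
well the planted quantities are recovered.  These power the package's
acceptance checks and are useful as calibration diagnostics in their own
right.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exposure import (
    balanced_groups,
    log_normalize,
    pc1_score,
    score_exposures,
    spearman_dose_response,
)
from .network import clr, infer_network, natural_connectivity
from .neutral import fit_sloan, grid_search_m, occupancy_abundance
from .simulate import (
    CohortSpec,
    make_planted_graph,
    simulate_cohort,
    simulate_exposures,
    simulate_graph_community,
    simulate_neutral_community,
)
from .stats import distance, fit_associations, permanova


def sloan_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    m_true: float = 0.1,
    N_t: float = 10_000,
    n_taxa: int = 300,
    n_samples: int = 200,
    depth: int = 10_000,
) -> dict:
    """Simulate neutral communities and refit: m, R² and AIC selection."""
    ms, r2s, wins, instances = [], [], 0, []
    for k in range(n_seeds):
        table, _ = simulate_neutral_community(
            n_taxa, n_samples, N_t, m_true, depth, seed=base_seed + k
        )
        pts = occupancy_abundance(table)
        fit = fit_sloan(pts, float(table.library_sizes().mean()))
        ms.append(fit.m)
        r2s.append(fit.R2)
        wins += fit.aic_neutral < min(fit.aic_binomial, fit.aic_poisson)
        instances.append((pts, fit))
    return {
        "m_true": m_true,
        "m_median": float(np.median(ms)),
        "m_values": ms,
        "r2_median": float(np.median(r2s)),
        "aic_neutral_wins": int(wins),
        "n_seeds": n_seeds,
        "instances": instances,
    }


def grid_agreement(instances, step: float = 1e-4) -> dict:
    """NLS fit vs dense grid search over m on every instance."""
    max_dm, all_ok = 0.0, True
    for pts, fit in instances:
        m_grid, rss_grid = grid_search_m(pts, fit.N_t, step=step)
        dm = abs(fit.m - m_grid)
        max_dm = max(max_dm, dm)
        ok = dm <= step or fit.rss_neutral <= rss_grid + 1e-12
        all_ok = all_ok and ok
    return {"max_abs_m_difference": max_dm, "all_within_one_step": all_ok}


def network_chain_recovery(
    n_seeds: int = 10,
    base_seed: int = 0,
    n_bacteria: int = 40,
    n_fungi: int = 20,
    n_samples: int = 300,
) -> dict:
    """Edge precision/recall against a planted chain graph (pre-filter)."""
    precs, recs = [], []
    for k in range(n_seeds):
        seed = base_seed + k
        edges = make_planted_graph("chain", n_bacteria + n_fungi, seed=seed)
        tb, tf, truth = simulate_graph_community(
            edges, n_bacteria, n_fungi, n_samples, seed=seed
        )
        net = infer_network(clr(tb), clr(tf), seed=seed)
        est = {frozenset((u, v)) for u, v in net.graph.edges}
        true = {frozenset((u, v)) for u, v, _ in truth.graph_edges}
        tp = len(est & true)
        precs.append(tp / len(est) if est else 1.0)
        recs.append(tp / len(true))
    return {
        "precision_median": float(np.median(precs)),
        "recall_median": float(np.median(recs)),
        "precisions": precs,
        "recalls": recs,
    }


def network_null_density(
    n_seeds: int = 10,
    base_seed: int = 0,
    n_bacteria: int = 25,
    n_fungi: int = 15,
    n_samples: int = 200,
) -> dict:
    """Selected edge density on independent (empty-graph) data."""
    p = n_bacteria + n_fungi
    possible = p * (p - 1) / 2
    dens = []
    for k in range(n_seeds):
        seed = base_seed + k
        tb, tf, _ = simulate_graph_community(
            [], n_bacteria, n_fungi, n_samples, seed=seed
        )
        net = infer_network(clr(tb), clr(tf), seed=seed)
        dens.append(net.graph.number_of_edges() / possible)
    return {"density_median": float(np.median(dens)), "densities": dens}


def _walk_sum_connectivity(A: np.ndarray, terms: int = 60) -> float:
    """Independent oracle: ln(sum_k tr(A^k)/k! / n) via explicit powers."""
    n = A.shape[0]
    P = np.eye(n)
    total, fact = 0.0, 1.0
    for k in range(terms):
        total += np.trace(P) / fact
        P = P @ A
        fact *= k + 1
    return float(np.log(total / n))


def natural_connectivity_checks(
    rng_seed: int = 0, exhaustive_n: int = 6, n_random_8: int = 200
) -> dict:
    """Closed forms plus eigen-vs-walk-sum agreement on small graphs.

    Exhaustive over all labelled graphs up to ``exhaustive_n`` nodes
    (batched), plus random graphs on 7-8 nodes.
    """
    import networkx as nx

    k3 = nx.complete_graph(3)
    p3 = nx.path_graph(3)
    empty = nx.empty_graph(5)
    out = {
        "k3": natural_connectivity(k3),
        "p3": natural_connectivity(p3),
        "edgeless": natural_connectivity(empty),
    }
    # star-hub attack: removing the hub leaves an edgeless graph
    from .network import attack_stability

    star = nx.star_graph(5)
    curve = attack_stability(star, fraction=1.0)
    out["star_first_removed_is_hub"] = curve.removal_order[0] == 0
    out["star_connectivity_after_hub"] = float(curve.connectivity[1])

    max_dev = 0.0
    for n in range(2, exhaustive_n + 1):
        pairs = list(itertools.combinations(range(n), 2))
        n_graphs = 2 ** len(pairs)
        masks = (
            np.arange(n_graphs)[:, None] >> np.arange(len(pairs))[None, :]
        ) & 1
        A = np.zeros((n_graphs, n, n))
        for e, (i, j) in enumerate(pairs):
            A[:, i, j] = masks[:, e]
            A[:, j, i] = masks[:, e]
        lam = np.linalg.eigvalsh(A)
        from scipy.special import logsumexp

        eig_nc = logsumexp(lam, axis=1) - np.log(n)
        # batched walk-sum oracle
        P = np.broadcast_to(np.eye(n), A.shape).copy()
        total = np.zeros(n_graphs)
        fact = 1.0
        for k in range(60):
            total += np.trace(P, axis1=1, axis2=2) / fact
            P = P @ A
            fact *= k + 1
        walk_nc = np.log(total / n)
        max_dev = max(max_dev, float(np.abs(eig_nc - walk_nc).max()))
    rng = np.random.default_rng(rng_seed)
    for _ in range(n_random_8):
        n = int(rng.integers(7, 9))
        A = np.triu((rng.random((n, n)) < 0.4).astype(float), 1)
        A = A + A.T
        g = nx.from_numpy_array(A)
        max_dev = max(
            max_dev, abs(natural_connectivity(g) - _walk_sum_connectivity(A))
        )
    out["max_eigen_vs_walk_deviation"] = max_dev
    return out


def permanova_type1(
    n_sims: int = 500,
    n_perm: int = 99,
    n_samples: int = 30,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate on structureless data with random labels."""
    rng = np.random.default_rng(base_seed)
    rejections = 0
    labels = np.array(["a", "b"] * (n_samples // 2))
    for k in range(n_sims):
        X = rng.gamma(1.0, size=(n_samples, 10))
        D = distance(pd.DataFrame(X), "bray_curtis")
        res = permanova(
            D, rng.permutation(labels), n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rejections += res.p <= alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}


def dose_response_power(
    n_seeds: int = 50,
    base_seed: int = 0,
    effect: float = 0.5,
    taxon: str = "OTU_B0001",
) -> dict:
    """Power to detect a planted log-linear dose effect at n=204."""
    hits, null_ps = 0, []
    for k in range(n_seeds):
        spec = CohortSpec(
            planted_dose_taxa=[(taxon, effect)] if effect else [],
            seed=base_seed + k,
        )
        bundle, _ = simulate_cohort(spec)
        es = score_exposures(bundle.exposures)
        cheek = bundle.meta.index[bundle.meta.site == "cheek"]
        ra = bundle.bacteria.select_samples(cheek).relative_abundance()[taxon]
        sc = es.score.reindex(bundle.meta.loc[cheek, "subject_id"]).to_numpy()
        rho, p = spearman_dose_response(ra.to_numpy(), sc)
        if effect:
            hits += (rho > 0) and (p < 0.05)
        else:
            null_ps.append(p)
    out = {"n_seeds": n_seeds, "effect": effect}
    if effect:
        out["power"] = hits / n_seeds
    else:
        out["null_p_values"] = null_ps
        out["ks_uniform_p"] = float(sps.kstest(null_ps, "uniform").pvalue)
    return out


def fdr_null_proportion(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_features: int = 200,
    n_samples: int = 100,
    q_threshold: float = 0.25,
) -> dict:
    """Share of null simulations producing any (false) BH discovery."""
    fdps = []
    rng = np.random.default_rng(base_seed)
    for _ in range(n_seeds):
        raw = rng.gamma(1.0, size=(n_samples, n_features))
        ra = raw / raw.sum(axis=1, keepdims=True)
        feats = pd.DataFrame(ra, index=[f"S{i}" for i in range(n_samples)])
        feats.columns = [f"F{i}" for i in range(n_features)]
        meta = pd.DataFrame(
            {
                "x": rng.normal(size=n_samples),
                "grp": rng.choice(["u", "v"], n_samples),
            },
            index=feats.index,
        )
        res = fit_associations(feats, meta, ["x", "grp"], q_threshold)
        flagged = int(res["significant"].sum())
        fdps.append(1.0 if flagged else 0.0)  # all discoveries are false
    return {"mean_fdp": float(np.mean(fdps)), "n_seeds": n_seeds}


def balanced_grouping_checks() -> dict:
    """Group-size arithmetic for the study n and a sweep of (n, k)."""
    rng = np.random.default_rng(0)
    sizes_202 = sorted(
        balanced_groups(pd.Series(rng.normal(size=202)), 8).value_counts()
    )
    max_spread = 0
    for n in (8, 13, 50, 101, 202, 204, 333):
        for k in (2, 3, 5, 8):
            sizes = balanced_groups(pd.Series(rng.normal(size=n)), k).value_counts()
            max_spread = max(max_spread, int(sizes.max() - sizes.min()))
    return {"sizes_202_8": [int(s) for s in sizes_202], "max_spread": max_spread}


def pc1_explained_variance_both_modes(seed: int = 0) -> dict:
    """PC1 explained variance, standardised and unstandardised columns.

    Computed on a synthetic cohort's exposure table; both standardisation
    modes are reported because the convention changes the figure.
    """
    expo, _ = simulate_exposures(CohortSpec(seed=seed), seed=seed)
    out = {}
    for tag, std in (("standardized", True), ("unstandardized", False)):
        es = pc1_score(log_normalize(expo, standardize=std))
        out[tag] = es.explained_variance
    return out
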