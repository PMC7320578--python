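"""Cross-domain association networks from compositional counts.

Counts from the bacterial (16S) and fungal (ITS) tables are prevalence-
filtered, centered-log-ratio transformed per domain, concatenated, and a
sparse conditional-dependence graph is estimated by per-node L1-penalised
regression (Meinshausen-Buhlmann neighborhood selection).  The penalty is
chosen by stability selection over random subsamples (StARS): the smallest
penalty whose monotonised average edge instability stays at or below the
target is retained.  Edge weights are the max-magnitude symmetrised
regression coefficients on column-standardised CLR data, which puts them
on a correlation-like scale; weak edges (|w| <= 0.15 by default) are then
discarded.  Robustness is quantified by natural connectivity — the log
average eigenvalue exponential of the 0/1 adjacency, a closed-walk count —
tracked while nodes are removed in order of decreasing betweenness
centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.linear_model import lasso_path

from .errors import EmptyTableError
from .tables import TaxonTable

logger = logging.getLogger(__name__)


@dataclass
class AssociationNetwork:
    """Signed, weighted cross-domain graph with selection metadata."""

    graph: nx.Graph  # nodes carry 'domain'; edges carry 'weight' and 'sign'
    penalty_path: np.ndarray | None = None
    chosen_penalty: float | None = None
    stability_threshold: float | None = None
    n_subsamples: int | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node1": u,
                "node2": v,
                "weight": d["weight"],
                "sign": d["sign"],
                "domain_pair": "-".join(
                    sorted(
                        (self.graph.nodes[u]["domain"], self.graph.nodes[v]["domain"])
                    )
                ),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["node1", "node2", "weight", "sign", "domain_pair"]
        )


@dataclass
class AttackCurve:
    """Natural connectivity along a betweenness-ranked node removal."""

    removal_order: list
    connectivity: np.ndarray  # length = removals + 1; [0] is intact value
    percent_reduction: np.ndarray  # vs. intact, same length


def prevalence_filter(
    table: TaxonTable, min_prev: float = 0.25
) -> TaxonTable:
    """Keep taxa detected (count > 0) in >= ``min_prev`` of samples.

    The boundary is inclusive: a taxon present in exactly 25% of samples
    is retained under the default.
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        raise EmptyTableError("empty taxon table")
    prev = (table.counts.to_numpy() > 0).mean(axis=0)
    keep = table.taxon_ids[prev >= min_prev]
    if len(keep) == 0:
        raise EmptyTableError(
            f"prevalence filter at {min_prev} removed all {table.n_taxa} taxa"
        )
    logger.info(
        "prevalence filter %.2f: %d -> %d taxa", min_prev, table.n_taxa, len(keep)
    )
    return table.select_taxa(keep)


def clr(table: TaxonTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform per sample: log((x+c)/g(x+c))."""
    x = table.counts.to_numpy(dtype=float) + pseudocount
    logx = np.log(x)
    out = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.taxon_ids)


def _neighborhood_edges(X: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Boolean (n_alphas, p, p) directed selection arrays from lasso paths.

    X must be column-standardised.  ``lasso_path`` solves
    ``1/(2n) ||y - Xw||^2 + alpha ||w||_1`` for all alphas at once.
    """
    n, p = X.shape
    sel = np.zeros((len(alphas), p, p), dtype=bool)
    idx = np.arange(p)
    for j in range(p):
        y = X[:, j]
        others = idx != j
        _, coefs, _ = lasso_path(X[:, others], y, alphas=alphas, max_iter=5000)
        # lasso_path returns coefs for alphas in the given (descending) order
        sel[:, j, others] = (np.abs(coefs) > 1e-10).T
    return sel


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def default_penalty_path(X: np.ndarray, n_path: int = 20) -> np.ndarray:
    """20 log-spaced penalties from the max-correlation bound down 1e-2."""
    n = X.shape[0]
    G = X.T @ X / n
    np.fill_diagonal(G, 0.0)
    lam_max = float(np.abs(G).max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 1e-2, n_path)


def infer_network(
    clr_bacteria: pd.DataFrame,
    clr_fungi: pd.DataFrame,
    penalty_path: np.ndarray | None = None,
    n_subsamples: int = 50,
    stability_threshold: float = 0.05,
    seed: int = 0,
    domains: tuple[str, str] = ("bacteria", "fungi"),
) -> AssociationNetwork:
    """Neighborhood-selection graph over concatenated CLR matrices.

    Stability selection: over ``n_subsamples`` subsamples of size
    ``floor(0.8 n)`` drawn without replacement, compute edge selection
    frequencies along the penalty path (OR rule over the two directed
    regressions); the average edge instability ``2 theta (1 - theta)`` is
    monotonised from the sparse end and the smallest penalty keeping it
    at or below ``stability_threshold`` is chosen.  If no penalty
    qualifies, the densest path entry is used with a warning.  The final
    graph is refit on the full data at the chosen penalty; weights are
    max-magnitude symmetrised coefficients.
    """
    if list(clr_bacteria.index) != list(clr_fungi.index):
        raise ValueError("CLR matrices must share sample order")
    X = np.hstack([clr_bacteria.to_numpy(), clr_fungi.to_numpy()])
    node_ids = list(clr_bacteria.columns) + list(clr_fungi.columns)
    node_domain = [domains[0]] * clr_bacteria.shape[1] + [
        domains[1]
    ] * clr_fungi.shape[1]
    n, p = X.shape
    if p < 4:
        raise ValueError("need at least 4 taxa across both domains")
    X = _standardize(X)
    if penalty_path is None:
        penalty_path = default_penalty_path(X)
    alphas = np.sort(np.asarray(penalty_path, dtype=float))[::-1]

    rng = np.random.default_rng(seed)
    # canonical StARS size 10*sqrt(n), capped at 0.8n so small n stay safe;
    # larger overlapping subsamples underestimate instability and select
    # over-dense graphs
    n_sub = max(2, min(int(np.floor(10 * np.sqrt(n))), int(np.floor(0.8 * n))))
    freq = np.zeros((len(alphas), p, p))
    for _ in range(n_subsamples):
        take = rng.choice(n, size=n_sub, replace=False)
        Xs = _standardize(X[take])
        sel = _neighborhood_edges(Xs, alphas)
        freq += sel | sel.transpose(0, 2, 1)  # OR rule
    theta = freq / n_subsamples
    iu = np.triu_indices(p, k=1)
    instab = (2 * theta * (1 - theta))[:, iu[0], iu[1]].mean(axis=1)
    instab_mono = np.maximum.accumulate(instab)  # from sparsest (largest alpha)
    ok = np.nonzero(instab_mono <= stability_threshold)[0]
    if len(ok):
        chosen_idx = int(ok.max())  # smallest qualifying penalty
    else:
        chosen_idx = len(alphas) - 1
        logger.warning(
            "no penalty met instability <= %.3g; returning densest graph",
            stability_threshold,
        )
    alpha_star = float(alphas[chosen_idx])

    # refit on full data at the chosen penalty to get signed weights
    coefs = np.zeros((p, p))
    idx = np.arange(p)
    for j in range(p):
        others = idx != j
        _, cj, _ = lasso_path(
            X[:, others], X[:, j], alphas=[alpha_star], max_iter=5000
        )
        coefs[j, others] = cj[:, 0]

    g = nx.Graph()
    for nid, dom, ab in zip(node_ids, node_domain, X.mean(axis=0)):
        g.add_node(nid, domain=dom)
    for a in range(p):
        for b in range(a + 1, p):
            w_ab, w_ba = coefs[a, b], coefs[b, a]
            if w_ab == 0 and w_ba == 0:
                continue
            w = w_ab if abs(w_ab) >= abs(w_ba) else w_ba
            g.add_edge(
                node_ids[a],
                node_ids[b],
                weight=float(w),
                sign="positive" if w > 0 else "negative",
            )
    return AssociationNetwork(
        graph=g,
        penalty_path=alphas,
        chosen_penalty=alpha_star,
        stability_threshold=stability_threshold,
        n_subsamples=n_subsamples,
        seed=seed,
        meta={"instability_path": instab_mono},
    )


def filter_weak_edges(
    net: AssociationNetwork, min_abs: float = 0.15
) -> AssociationNetwork:
    """Drop edges with |weight| <= ``min_abs``; isolated nodes kept."""
    g = net.graph.copy()
    weak = [
        (u, v) for u, v, d in g.edges(data=True) if abs(d["weight"]) <= min_abs
    ]
    g.remove_edges_from(weak)
    logger.info("edge filter |w| <= %.3g removed %d edges", min_abs, len(weak))
    return AssociationNetwork(
        graph=g,
        penalty_path=net.penalty_path,
        chosen_penalty=net.chosen_penalty,
        stability_threshold=net.stability_threshold,
        n_subsamples=net.n_subsamples,
        seed=net.seed,
        meta=dict(net.meta),
    )


def natural_connectivity(net: AssociationNetwork | nx.Graph) -> float:
    """ln(mean(exp(eigenvalues))) of the unweighted 0/1 adjacency."""
    g = net.graph if isinstance(net, AssociationNetwork) else net
    n = g.number_of_nodes()
    if n == 0:
        raise EmptyTableError("natural connectivity undefined for empty graph")
    A = nx.to_numpy_array(g, weight=None)
    lam = np.linalg.eigvalsh(A)
    return float(logsumexp(lam) - np.log(n))


def attack_stability(
    net: AssociationNetwork | nx.Graph, fraction: float = 1.0
) -> AttackCurve:
    """Remove nodes by descending intact-graph betweenness, tracking NC.

    Ties are broken by degree (descending) then lexical node id; the
    ranking is computed once on the intact unweighted graph and not
    refreshed after removals.  ``percent_reduction`` is relative to the
    intact natural connectivity (0 when the intact value is 0).
    """
    g = (net.graph if isinstance(net, AssociationNetwork) else net).copy()
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    bet = nx.betweenness_centrality(g, normalized=True)
    deg = dict(g.degree())
    order = sorted(g.nodes, key=lambda v: (-bet[v], -deg[v], str(v)))
    n_remove = max(1, int(np.floor(fraction * g.number_of_nodes())))
    order = order[:n_remove]
    nc = [natural_connectivity(g)]
    for v in order:
        g.remove_node(v)
        nc.append(natural_connectivity(g) if g.number_of_nodes() else 0.0)
    nc = np.asarray(nc)
    base = nc[0]
    pct = np.zeros_like(nc) if base == 0 else (base - nc) / base * 100.0
    return AttackCurve(removal_order=order, connectivity=nc, percent_reduction=pct)


def network_summary(net: AssociationNetwork) -> dict:
    """Average degree, degree histogram, and sign-by-domain edge counts."""
    g = net.graph
    degs = [d for _, d in g.degree()]
    hist: dict[int, int] = {}
    for d in degs:
        hist[d] = hist.get(d, 0) + 1
    cats = {
        (s, dp): 0
        for s in ("positive", "negative")
        for dp in ("bacteria-bacteria", "bacteria-fungi", "fungi-fungi")
    }
    for u, v, d in g.edges(data=True):
        dp = "-".join(sorted((g.nodes[u]["domain"], g.nodes[v]["domain"])))
        cats[(d["sign"], dp)] += 1
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "average_degree": float(np.mean(degs)) if degs else 0.0,
        "degree_histogram": dict(sorted(hist.items())),
        "edge_counts": {f"{s}_{dp}": c for (s, dp), c in cats.items()},
    }
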