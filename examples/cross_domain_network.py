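"""Infer a cross-domain bacteria-fungi network and test its robustness.

Plants a signed chain graph over 40 bacterial and 20 fungal taxa,
simulates logistic-normal counts, recovers the graph by CLR +
neighborhood selection with stability (StARS) penalty choice, applies
the |0.15| weak-edge filter, and runs a betweenness-ranked node attack
tracking natural connectivity.
"""

from skinpah import (
    attack_stability,
    clr,
    filter_weak_edges,
    infer_network,
    make_planted_graph,
    network_summary,
    simulate_graph_community,
)

edges = make_planted_graph("chain", 60, seed=0)
bact, fungi, truth = simulate_graph_community(
    edges, n_bacteria=40, n_fungi=20, n_samples=300, seed=0
)
net = infer_network(clr(bact), clr(fungi), seed=0)

true = {frozenset((u, v)) for u, v, _ in truth.graph_edges}
est = {frozenset(e) for e in net.graph.edges}
tp = len(true & est)
print(f"planted edges    : {len(true)}")
print(f"recovered edges  : {len(est)}  (precision {tp/len(est):.2f}, recall {tp/len(true):.2f})")

net = filter_weak_edges(net, min_abs=0.15)
summary = network_summary(net)
print(f"after |w|<=0.15 filter: {summary['n_edges']} edges, "
      f"average degree {summary['average_degree']:.2f}")
print(f"edge counts by sign x domain: {summary['edge_counts']}")

curve = attack_stability(net)
k = max(1, len(curve.removal_order) // 10)
print(
    f"natural connectivity intact: {curve.connectivity[0]:.3f}; after removing "
    f"the top-betweenness 10% of nodes it drops by "
    f"{curve.percent_reduction[k]:.1f}%"
)
print(
    "\nA sparser, less integrated network loses connectivity faster under"
    "\ntargeted attack - the contrast used to compare healthy and affected"
    "\nskin-site networks."
)
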