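"""Network topology characterization: degrees, components, paths, clustering.

Mirrors the standard descriptive battery for coexpression graphs: degree
distribution (with a two-sample Kolmogorov-Smirnov comparison across
networks), largest connected component, mean shortest path length within the
LCC, and the global clustering coefficient (transitivity).
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
from scipy import stats

from .containers import CoexpressionNetwork


@dataclass
class TopologySummary:
    """One row of the per-timepoint topology table."""

    timepoint: str
    n_nodes: int
    n_links: int
    lcc_size: int
    mean_path_length: float
    global_clustering: float

    def as_dict(self) -> dict:
        return asdict(self)


def degree_sequence(net: CoexpressionNetwork) -> dict[str, int]:
    """Degree of every node of the shared node set (isolated nodes included)."""
    return {g: int(d) for g, d in net.graph.degree(net.node_ids)}


def ks_compare_degrees(
    net_a: CoexpressionNetwork, net_b: CoexpressionNetwork
) -> tuple[float, float]:
    """Two-sample KS test (asymptotic two-sided p) on the full degree sequences."""
    da = list(degree_sequence(net_a).values())
    db = list(degree_sequence(net_b).values())
    if not da or not db:
        raise ValueError("both networks need a non-empty node set")
    res = stats.ks_2samp(da, db, method="asymp")
    return float(res.statistic), float(res.pvalue)


def largest_connected_component(net: CoexpressionNetwork) -> list[str]:
    """Maximum-cardinality component; ties go to the lexicographically smallest member."""
    components = list(nx.connected_components(net.graph))
    best = min(components, key=lambda c: (-len(c), min(c)))
    return sorted(best)


def mean_shortest_path(net: CoexpressionNetwork, within: list[str] | None = None) -> float:
    """Mean unweighted shortest-path length over unordered pairs of ``within``.

    ``within`` defaults to the largest connected component; an error is
    raised if any pair of the subset is unreachable.  Pairs spanning
    components are never averaged with a sentinel distance.
    """
    if within is None:
        within = largest_connected_component(net)
    subset = sorted(within)
    if len(subset) < 2:
        raise ValueError("need at least two nodes to average path lengths")
    members = set(subset)
    total = 0
    n_pairs = 0
    for u in subset:
        lengths = nx.single_source_shortest_path_length(net.graph, u)
        for v in subset:
            if v <= u:
                continue
            if v not in lengths:
                raise ValueError(f"subset is disconnected: no path from {u!r} to {v!r}")
            total += lengths[v]
            n_pairs += 1
    assert n_pairs == len(members) * (len(members) - 1) // 2
    return total / n_pairs


def global_clustering(net: CoexpressionNetwork) -> float:
    """Transitivity: 3 * triangles / connected triples (0 when no triples)."""
    return float(nx.transitivity(net.graph))


def topology_summary(net: CoexpressionNetwork) -> TopologySummary:
    """Table-1-style row for one network."""
    lcc = largest_connected_component(net)
    mpl = mean_shortest_path(net, lcc) if len(lcc) >= 2 else float("nan")
    return TopologySummary(
        timepoint=net.timepoint,
        n_nodes=net.n_nodes,
        n_links=net.n_links,
        lcc_size=len(lcc),
        mean_path_length=mpl,
        global_clustering=global_clustering(net),
    )
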