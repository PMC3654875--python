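"""Temporal rewiring statistics across the ordered network series.

Quantifies how much of the network survives from one timepoint to the next
(conserved links), how genes move between centrality categories
(transition flows, stability and transient-prominence lists) and how node
degrees change over the two transitions (the nine increase/decrease/no-change
patterns).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .containers import TIMEPOINTS, CoexpressionNetwork
from .roles import CATEGORIES

PROMINENT = ("HB", "HNB", "NHB")  # every category except NHNB
DEGREE_LABELS = ("increase", "decrease", "no change")


@dataclass
class ConservedLinks:
    """Shared-edge count between two networks, under all three denominators."""

    count: int
    fraction_of_earlier: float
    fraction_of_later: float
    fraction_of_union: float


@dataclass
class TransitionTable:
    """Per-gene category triples plus 4x4 flow counts per transition."""

    triples: pd.DataFrame  # genes x (pre, mid, post) categories
    flows: dict[str, pd.DataFrame]  # "pre->mid", "mid->post" -> 4x4 counts


@dataclass
class StabilityReport:
    """Who keeps, and who only briefly holds, a prominent network position."""

    stable_genes: list[str]
    always_hub: list[str]
    always_bottleneck: list[str]
    prominent_in_exactly_one: dict[str, list[str]]
    venn_counts: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)


def _fraction(count: int, denom: int) -> float:
    if denom == 0:
        # vacuous case: two empty edge sets are fully conserved
        return 1.0 if count == 0 else 0.0
    return count / denom


def conserved_links(net_a: CoexpressionNetwork, net_b: CoexpressionNetwork) -> ConservedLinks:
    """Edges shared by two networks over the same node set.

    The headline statistic is ``fraction_of_earlier`` (shared links as a
    fraction of the earlier network's links); the later-network and union
    denominators are reported alongside.
    """
    if set(net_a.node_ids) != set(net_b.node_ids):
        raise ValueError("networks must share an identical node set")
    ea, eb = net_a.edge_set(), net_b.edge_set()
    shared = len(ea & eb)
    return ConservedLinks(
        count=shared,
        fraction_of_earlier=_fraction(shared, len(ea)),
        fraction_of_later=_fraction(shared, len(eb)),
        fraction_of_union=_fraction(shared, len(ea | eb)),
    )


def _ordered_timepoints(keys) -> list[str]:
    tps = [tp for tp in TIMEPOINTS if tp in keys]
    if len(tps) != len(list(keys)):
        extra = set(keys) - set(TIMEPOINTS)
        raise ValueError(f"unknown timepoint labels: {sorted(extra)}")
    return tps


def category_transitions(role_tables: dict[str, pd.DataFrame]) -> TransitionTable:
    """Category triple per gene and 4x4 flow counts for each transition."""
    tps = _ordered_timepoints(role_tables.keys())
    if len(tps) < 2:
        raise ValueError("need at least two timepoints to compute transitions")
    genes = sorted(role_tables[tps[0]].index)
    for tp in tps:
        missing = set(genes) ^ set(role_tables[tp].index)
        if missing:
            raise ValueError(
                f"gene set mismatch at timepoint {tp!r}: {sorted(missing)[:5]}"
            )
    triples = pd.DataFrame(
        {tp: role_tables[tp].loc[genes, "category"] for tp in tps}, index=pd.Index(genes, name="gene_id")
    )
    flows: dict[str, pd.DataFrame] = {}
    for a, b in zip(tps[:-1], tps[1:]):
        counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
        for _, row in triples.iterrows():
            counts.loc[row[a], row[b]] += 1
        flows[f"{a}->{b}"] = counts
    return TransitionTable(triples=triples, flows=flows)


def stability_report(table: TransitionTable) -> StabilityReport:
    """Stable, always-hub, always-bottleneck and transiently prominent genes."""
    triples = table.triples
    tps = list(triples.columns)
    stable = [
        g
        for g, row in triples.iterrows()
        if len(set(row)) == 1 and row.iloc[0] in PROMINENT
    ]
    always_hub = [
        g for g, row in triples.iterrows() if all(c in ("HB", "HNB") for c in row)
    ]
    always_bottleneck = [
        g for g, row in triples.iterrows() if all(c in ("HB", "NHB") for c in row)
    ]
    prominent_in_exactly_one: dict[str, list[str]] = {tp: [] for tp in tps}
    for g, row in triples.iterrows():
        hits = [tp for tp in tps if row[tp] in PROMINENT]
        if len(hits) == 1:
            prominent_in_exactly_one[hits[0]].append(g)
    venn: dict[str, dict[str, dict[str, int]]] = {}
    for a, b in zip(tps[:-1], tps[1:]):
        venn[f"{a}&{b}"] = {}
        for cat in CATEGORIES:
            in_a = set(triples.index[triples[a] == cat])
            in_b = set(triples.index[triples[b] == cat])
            venn[f"{a}&{b}"][cat] = {
                "only_earlier": len(in_a - in_b),
                "both": len(in_a & in_b),
                "only_later": len(in_b - in_a),
            }
    return StabilityReport(
        stable_genes=sorted(stable),
        always_hub=sorted(always_hub),
        always_bottleneck=sorted(always_bottleneck),
        prominent_in_exactly_one={tp: sorted(v) for tp, v in prominent_in_exactly_one.items()},
        venn_counts=venn,
    )


def degree_change_patterns(
    nets: dict[str, CoexpressionNetwork],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nine-cell degree-change pattern counts plus the per-gene pattern table.

    Each transition is labeled increase / decrease / no change by the exact
    integer degree difference; the pattern is the ordered pair of labels over
    the two transitions.
    """
    tps = _ordered_timepoints(nets.keys())
    if len(tps) != 3:
        raise ValueError("degree-change patterns are defined over exactly 3 timepoints")
    node_sets = [set(nets[tp].node_ids) for tp in tps]
    if node_sets[0] != node_sets[1] or node_sets[1] != node_sets[2]:
        raise ValueError("networks must share an identical node set")
    genes = sorted(node_sets[0])
    degs = {tp: dict(nets[tp].graph.degree(genes)) for tp in tps}

    def label(delta: int) -> str:
        return "increase" if delta > 0 else "decrease" if delta < 0 else "no change"

    per_gene = pd.DataFrame(
        {
            "first_transition": [label(degs[tps[1]][g] - degs[tps[0]][g]) for g in genes],
            "second_transition": [label(degs[tps[2]][g] - degs[tps[1]][g]) for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    counts = pd.DataFrame(0, index=list(DEGREE_LABELS), columns=list(DEGREE_LABELS))
    for first, second in product(DEGREE_LABELS, DEGREE_LABELS):
        counts.loc[first, second] = int(
            ((per_gene["first_transition"] == first) & (per_gene["second_transition"] == second)).sum()
        )
    return counts, per_gene


def rewiring_summary(
    nets: dict[str, CoexpressionNetwork], role_tables: dict[str, pd.DataFrame]
) -> dict:
    """JSON-ready summary of all rewiring statistics for one run."""
    tps = _ordered_timepoints(nets.keys())
    conserved = {}
    for a, b in zip(tps[:-1], tps[1:]):
        c = conserved_links(nets[a], nets[b])
        conserved[f"{a}->{b}"] = {
            "count": c.count,
            "fraction_of_earlier": c.fraction_of_earlier,
            "fraction_of_later": c.fraction_of_later,
            "fraction_of_union": c.fraction_of_union,
        }
    table = category_transitions(role_tables)
    report = stability_report(table)
    counts, _ = degree_change_patterns(nets)
    return {
        "conserved_links": conserved,
        "category_flows": {k: v.to_dict() for k, v in table.flows.items()},
        "stable_genes": report.stable_genes,
        "always_hub": report.always_hub,
        "always_bottleneck": report.always_bottleneck,
        "prominent_in_exactly_one": report.prominent_in_exactly_one,
        "venn_counts": report.venn_counts,
        "degree_change_pattern_counts": counts.to_dict(),
    }
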