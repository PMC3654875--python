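"""Hub/bottleneck role classification via statistical-outlier fences.

Hubs are nodes whose degree is a statistical outlier of their network's
degree distribution; bottlenecks are outliers by betweenness centrality.
Crossing the two criteria yields four exclusive categories: hub-bottleneck
(HB), hub-nonbottleneck (HNB), nonhub-bottleneck (NHB) and
nonhub-nonbottleneck (NHNB).  "Outlier" is operationalized as exceeding the
Tukey upper fence Q3 + 1.5*IQR of the same network's score distribution; the
multiplier and quartile interpolation are configurable so alternative outlier
conventions can be matched.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CoexpressionNetwork

CATEGORIES = ("HB", "HNB", "NHB", "NHNB")


@dataclass(frozen=True)
class OutlierFences:
    """The two per-network outlier thresholds and the rule that produced them."""

    degree_fence: float
    betweenness_fence: float
    rule: str


def betweenness_scores(net: CoexpressionNetwork) -> dict[str, float]:
    """Raw (unnormalized) betweenness, endpoints excluded, ties split fractionally.

    Computed on the full graph: nodes in small components simply score low,
    and isolated nodes score exactly 0.
    """
    scores = nx.betweenness_centrality(net.graph, normalized=False)
    return {g: float(scores[g]) for g in net.node_ids}


def outlier_fence(scores, multiplier: float = 1.5, method: str = "linear") -> float:
    """Tukey upper fence Q3 + multiplier * IQR, quartiles by interpolation."""
    values = np.asarray(list(scores), dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 scores to place an outlier fence")
    q1, q3 = np.percentile(values, [25, 75], method=method)
    return float(q3 + multiplier * (q3 - q1))


def classify_nodes(
    net: CoexpressionNetwork, multiplier: float = 1.5, method: str = "linear"
) -> tuple[pd.DataFrame, OutlierFences]:
    """Per-node degree, betweenness and role category for one network."""
    degree = {g: int(d) for g, d in net.graph.degree(net.node_ids)}
    btw = betweenness_scores(net)
    deg_fence = outlier_fence(degree.values(), multiplier, method)
    btw_fence = outlier_fence(btw.values(), multiplier, method)
    fences = OutlierFences(
        degree_fence=deg_fence,
        betweenness_fence=btw_fence,
        rule=f"upper Tukey fence: Q3 + {multiplier}*IQR, quartile method {method!r}",
    )
    records = []
    for g in net.node_ids:
        hub = degree[g] > deg_fence
        bottleneck = btw[g] > btw_fence
        category = {
            (True, True): "HB",
            (True, False): "HNB",
            (False, True): "NHB",
            (False, False): "NHNB",
        }[(hub, bottleneck)]
        records.append(
            {
                "gene_id": g,
                "timepoint": net.timepoint,
                "degree": degree[g],
                "betweenness": btw[g],
                "category": category,
            }
        )
    table = pd.DataFrame(records).set_index("gene_id")
    return table, fences
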