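"""Core in-memory containers shared by every pipeline stage.

Expression data live in a genes-by-samples :class:`pandas.DataFrame`; each
inferred coexpression network is a :class:`networkx.Graph` over a fixed node
set, wrapped together with its timepoint label.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: The ordered experimental conditions: at diagnosis, after 10-14 days of
#: treatment, and after 90 days of treatment.
TIMEPOINTS: tuple[str, ...] = ("pre", "mid", "post")


@dataclass
class ExpressionMatrix:
    """Log-scale expression values (genes x samples) with timepoint labels.

    Parameters
    ----------
    values
        Genes in rows (index = gene ids), samples in columns.
    timepoints
        Maps each sample id (index) to one of :data:`TIMEPOINTS`.
    """

    values: pd.DataFrame
    timepoints: pd.Series
    timepoint_order: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups[:5])}")
        if self.values.isna().any().any():
            bad = self.values.isna().stack()
            g, s = bad[bad].index[0]
            raise ValueError(f"missing expression value at gene {g!r}, sample {s!r}")
        missing = [s for s in self.values.columns if s not in self.timepoints.index]
        if missing:
            raise ValueError(f"samples without a timepoint label: {missing[:5]}")
        labels = set(self.timepoints.loc[list(self.values.columns)])
        unknown = labels - set(self.timepoint_order)
        if unknown:
            raise ValueError(
                f"unknown timepoint labels {sorted(unknown)}; "
                f"allowed labels are {list(self.timepoint_order)}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_at(self, timepoint: str) -> pd.DataFrame:
        """Expression submatrix (genes x samples) for one timepoint."""
        if timepoint not in self.timepoint_order:
            raise ValueError(
                f"unknown timepoint {timepoint!r}; allowed: {list(self.timepoint_order)}"
            )
        cols = [s for s in self.values.columns if self.timepoints[s] == timepoint]
        return self.values[cols]

    def n_samples_at(self, timepoint: str) -> int:
        return self.samples_at(timepoint).shape[1]


@dataclass
class CoexpressionNetwork:
    """Undirected simple graph of significant direct correlations at one timepoint.

    Every node of the shared node set is present even when isolated.  Edge
    attributes: ``r`` (zero-order Spearman correlation), ``min_abs_partial``
    (smallest first-order partial magnitude over all conditioners) and
    ``max_p`` (largest p-value across the zero- and first-order tests).
    """

    timepoint: str
    node_ids: tuple[str, ...]
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for node in self.node_ids:
            if node not in self.graph:
                self.graph.add_node(node)
        extra = set(self.graph.nodes) - set(self.node_ids)
        if extra:
            raise ValueError(f"graph contains nodes outside the node set: {sorted(extra)[:5]}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as canonically ordered (sorted) gene-id pairs."""
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}


def pair_capacity(n_nodes: int) -> int:
    """Number of candidate links of a simple undirected graph on ``n_nodes``."""
    if n_nodes < 0:
        raise ValueError("n_nodes must be non-negative")
    return n_nodes * (n_nodes - 1) // 2


def as_float_array(values: pd.DataFrame) -> np.ndarray:
    """Contiguous float64 view of an expression block."""
    return np.ascontiguousarray(values.to_numpy(dtype=np.float64))
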