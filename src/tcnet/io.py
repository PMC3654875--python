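"""Reading and writing the pipeline's plain-text artifacts.

Canonical tabular dialect: tab-separated UTF-8 with '.' decimals.  Expression
comes as a genes-by-samples TSV plus a two-column sample metadata TSV;
networks go out as per-edge TSV lists and GraphML.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import TIMEPOINTS, CoexpressionNetwork, ExpressionMatrix

logger = logging.getLogger(__name__)


def read_expression(
    path_expr: str | Path,
    path_meta: str | Path,
    timepoint_order: tuple[str, ...] = TIMEPOINTS,
) -> ExpressionMatrix:
    """Load and validate an expression TSV plus its sample-metadata TSV.

    The expression file's first column holds gene ids and its header row the
    sample ids; the metadata file has columns ``sample_id`` and ``timepoint``.
    """
    raw = pd.read_csv(path_expr, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()].unique()[0]
        raise ValueError(f"duplicated gene id in {path_expr}: {dup!r}")
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str), dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any() or converted.isna().any():
            gene = raw.index[(bad | converted.isna()).to_numpy()][0]
            raise ValueError(
                f"malformed numeric cell in {path_expr} at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
        values[col] = converted.to_numpy()

    meta = pd.read_csv(path_meta, sep="\t", dtype=str)
    required = {"sample_id", "timepoint"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata {path_meta} must have columns {sorted(required)}")
    unknown = set(meta["timepoint"]) - set(timepoint_order)
    if unknown:
        raise ValueError(
            f"unknown timepoint label(s) {sorted(unknown)} in {path_meta}; "
            f"allowed labels are {list(timepoint_order)}"
        )
    timepoints = pd.Series(meta["timepoint"].values, index=meta["sample_id"].values)
    unlabeled = [s for s in values.columns if s not in timepoints.index]
    if unlabeled:
        raise ValueError(f"samples missing a timepoint label: {unlabeled[:5]}")
    extra = [s for s in timepoints.index if s not in values.columns]
    if extra:
        logger.warning("metadata lists %d sample(s) absent from the matrix: %s", len(extra), extra[:5])
        timepoints = timepoints.drop(index=extra)
    return ExpressionMatrix(values=values, timepoints=timepoints, timepoint_order=timepoint_order)


def write_expression(expr: ExpressionMatrix, path_expr: str | Path, path_meta: str | Path) -> None:
    expr.values.to_csv(path_expr, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": list(expr.timepoints.index), "timepoint": list(expr.timepoints.values)}
    ).to_csv(path_meta, sep="\t", index=False)


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_node_list(path: str | Path) -> list[str]:
    """Gene ids from a one-column file or the gene_id column of a DE table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" in df.columns:
        if "selected" in df.columns:
            df = df[df["selected"].str.lower().isin(["true", "1"])]
        genes = list(df["gene_id"])
    else:
        genes = [g for g in pd.read_csv(path, sep="\t", header=None, dtype=str)[0]]
    if not genes:
        raise ValueError(f"node list {path} is empty")
    return sorted(set(genes))


def write_network(net: CoexpressionNetwork, edge_path: str | Path, graphml_path: str | Path | None = None) -> None:
    """Per-edge TSV (gene_a, gene_b, r, min_abs_partial, max_p) and optional GraphML."""
    rows = []
    for u, v, attrs in sorted(net.graph.edges(data=True)):
        a, b = sorted((u, v))
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "r": attrs.get("r", np.nan),
                "min_abs_partial": attrs.get("min_abs_partial", np.nan),
                "max_p": attrs.get("max_p", np.nan),
            }
        )
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "min_abs_partial", "max_p"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if graphml_path is not None:
        g = net.graph.copy()
        g.graph["timepoint"] = net.timepoint
        nx.write_graphml(g, graphml_path)


def read_network(edge_path: str | Path, node_ids: list[str], timepoint: str) -> CoexpressionNetwork:
    """Rebuild a network from its edge-list TSV and the shared node set."""
    graph = nx.Graph()
    graph.add_nodes_from(node_ids)
    df = pd.read_csv(edge_path, sep="\t")
    for _, row in df.iterrows():
        graph.add_edge(
            str(row["gene_a"]),
            str(row["gene_b"]),
            r=float(row["r"]),
            min_abs_partial=float(row["min_abs_partial"]),
            max_p=float(row["max_p"]),
        )
    return CoexpressionNetwork(timepoint=timepoint, node_ids=tuple(node_ids), graph=graph)


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
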