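"""End-to-end pipeline driver: expression -> node set -> networks -> reports.

Stages: differential expression screen (or a user-supplied node list), one
partial-correlation network per timepoint, topology summaries, hub/bottleneck
role tables, and the temporal rewiring summary.  Everything is written to the
output directory as TSV/GraphML/JSON plus a machine-readable run report that
captures the full configuration, so identical config+seed reproduces
identical outputs byte for byte.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import TIMEPOINTS, ExpressionMatrix
from . import diffexpr, io, metrics, pcnet, rewiring, roles

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    expr_path: str
    meta_path: str
    out_dir: str
    node_list_path: str | None = None
    contrast: tuple[str, str] = ("pre", "post")
    fdr_threshold: float = 0.05
    alpha: float = 0.01
    n_permutations: int = 0  # 0 skips the permutation-null validation
    run_permutation_null: bool = False
    fence_multiplier: float = 1.5
    quartile_method: str = "linear"
    seed: int = 0
    timepoints: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if len(self.timepoints) < 2:
            raise ValueError("need at least two ordered timepoints")


def run_pipeline(cfg: RunConfig, expr: ExpressionMatrix | None = None) -> dict:
    """Execute every stage, write all artifacts, return the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {**asdict(cfg), "contrast": list(cfg.contrast), "timepoints": list(cfg.timepoints)},
        "version": __version__,
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return report["stages"].setdefault(name, {})

    try:
        if expr is None:
            expr = io.read_expression(cfg.expr_path, cfg.meta_path, cfg.timepoints)
    except Exception as err:
        raise RuntimeError(f"stage 'read_expression' failed: {err}") from err

    info = stage("read_expression")
    info["n_genes"] = len(expr.gene_ids)
    info["n_samples"] = {tp: expr.n_samples_at(tp) for tp in cfg.timepoints}

    try:
        if cfg.node_list_path is not None:
            nodes = io.read_node_list(cfg.node_list_path)
            missing = [g for g in nodes if g not in set(expr.gene_ids)]
            if missing:
                raise ValueError(f"node list genes absent from expression: {missing[:5]}")
            stage("diffexpr")["skipped"] = "node list supplied"
            logger.info("differential expression skipped: node list supplied")
        else:
            table = diffexpr.fit_gene_models(expr, cfg.contrast, cfg.fdr_threshold)
            io.write_de_table(table, out / "diffexpr.tsv")
            nodes = diffexpr.select_node_set(table)
            info = stage("diffexpr")
            info["n_selected"] = len(nodes)
            info["n_up"] = int((table.loc[nodes, "direction"] == "up").sum())
            info["n_down"] = int((table.loc[nodes, "direction"] == "down").sum())
    except RuntimeError:
        raise
    except Exception as err:
        raise RuntimeError(f"stage 'diffexpr' failed: {err}") from err
    stage("node_set")["n_nodes"] = len(nodes)
    pd.Series(nodes).to_csv(out / "node_set.tsv", sep="\t", index=False, header=["gene_id"])

    sig = pcnet.SignificanceConfig(
        alpha=cfg.alpha,
        n_permutations=max(1, cfg.n_permutations),
        seed=cfg.seed,
    )
    nets, role_tables = {}, {}
    for tp in cfg.timepoints:
        try:
            net = pcnet.build_network(expr, tp, nodes, sig)
        except Exception as err:
            raise RuntimeError(f"stage 'network[{tp}]' failed: {err}") from err
        nets[tp] = net
        io.write_network(net, out / f"network_{tp}.tsv", out / f"network_{tp}.graphml")
        stage("network")[tp] = {"n_links": net.n_links}
        if cfg.run_permutation_null and cfg.n_permutations > 0:
            null = pcnet.permutation_null(expr, tp, nodes, sig)
            io.write_json(
                {
                    "observed_edge_count": null.observed_edge_count,
                    "null_max": null.null_max,
                    "exceeds_null": null.exceeds_null,
                    "null_counts": null.null_counts,
                },
                out / f"permutation_null_{tp}.json",
            )
            stage("permutation_null")[tp] = {
                "observed": null.observed_edge_count,
                "null_max": null.null_max,
                "exceeds_null": null.exceeds_null,
            }

    try:
        summaries = [metrics.topology_summary(nets[tp]).as_dict() for tp in cfg.timepoints]
        pd.DataFrame(summaries).to_csv(out / "topology.tsv", sep="\t", index=False)
        stage("graph_metrics")["topology"] = summaries
        ks = {}
        for a, b in zip(cfg.timepoints[:-1], cfg.timepoints[1:]):
            d, p = metrics.ks_compare_degrees(nets[a], nets[b])
            ks[f"{a}->{b}"] = {"D": d, "p": p}
        io.write_json(ks, out / "ks_degree.json")
        stage("graph_metrics")["ks_degree"] = ks
    except RuntimeError:
        raise
    except Exception as err:
        raise RuntimeError(f"stage 'graph_metrics' failed: {err}") from err

    try:
        for tp in cfg.timepoints:
            table, fences = roles.classify_nodes(nets[tp], cfg.fence_multiplier, cfg.quartile_method)
            role_tables[tp] = table
            table.to_csv(out / f"roles_{tp}.tsv", sep="\t")
            io.write_json(
                {
                    "degree_fence": fences.degree_fence,
                    "betweenness_fence": fences.betweenness_fence,
                    "rule": fences.rule,
                },
                out / f"fences_{tp}.json",
            )
            stage("roles")[tp] = {
                "category_counts": table["category"].value_counts().to_dict(),
                "degree_fence": fences.degree_fence,
                "betweenness_fence": fences.betweenness_fence,
            }
    except RuntimeError:
        raise
    except Exception as err:
        raise RuntimeError(f"stage 'roles' failed: {err}") from err

    if len(cfg.timepoints) == 3:
        try:
            summary = rewiring.rewiring_summary(nets, role_tables)
            io.write_json(summary, out / "rewiring.json")
            trans = rewiring.category_transitions(role_tables)
            _, per_gene = rewiring.degree_change_patterns(nets)
            per_gene_table = trans.triples.join(per_gene)
            per_gene_table.to_csv(out / "gene_status.tsv", sep="\t")
            stage("rewiring")["conserved_links"] = summary["conserved_links"]
            stage("rewiring")["n_stable_genes"] = len(summary["stable_genes"])
        except RuntimeError:
            raise
        except Exception as err:
            raise RuntimeError(f"stage 'rewiring' failed: {err}") from err

    io.write_json(report, out / "run_report.json")
    return report
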