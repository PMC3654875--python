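"""Synthetic three-timepoint expression data with planted conditional-dependence graphs.

The generator plants, for each timepoint, a sparse undirected graph (with
optional hub nodes), converts it into a valid Gaussian graphical model
precision matrix, and draws multivariate-normal expression samples whose
conditional-independence structure is exactly the planted graph.  Consecutive
timepoints share a controlled fraction of edges, and a chosen gene subset can
receive a mean shift in the post-treatment samples so the differential
expression screen has ground truth too.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import TIMEPOINTS, ExpressionMatrix, pair_capacity

#: Safety factor applied to the adjacency spectral radius when setting the
#: precision diagonal; 5% keeps the model comfortably positive definite while
#: realizing the strongest conditional dependence the planted graph allows.
PD_MARGIN = 1.05


@dataclass(frozen=True)
class PlantedGraph:
    """A known ground-truth conditional-dependence graph for one timepoint."""

    node_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    timepoint: str = "pre"

    def __post_init__(self) -> None:
        nodes = set(self.node_ids)
        if len(nodes) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if (u, v) != tuple(sorted((u, v))):
                raise ValueError(f"edge {(u, v)} not canonically ordered")
            if u not in nodes or v not in nodes:
                raise ValueError(f"edge endpoint outside node set: {(u, v)}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree_of(self, node: str) -> int:
        return sum(node in e for e in self.edges)

    def adjacency(self) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.node_ids)}
        a = np.zeros((len(self.node_ids),) * 2)
        for u, v in self.edges:
            a[index[u], index[v]] = a[index[v], index[u]] = 1.0
        return a


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated study: one planted graph per timepoint."""

    graphs: dict[str, PlantedGraph]
    overlap_requested: float
    shifted_genes: frozenset[str]
    shift_size: float
    seed: int

    def __post_init__(self) -> None:
        node_sets = {tp: set(g.node_ids) for tp, g in self.graphs.items()}
        first = next(iter(node_sets.values()))
        if any(s != first for s in node_sets.values()):
            raise ValueError("planted graphs must share an identical node set")
        if not self.shifted_genes <= first:
            raise ValueError("shifted_genes must be a subset of the node set")


def _gene_ids(n_genes: int, prefix: str = "G") -> tuple[str, ...]:
    width = len(str(n_genes - 1))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(n_genes))


def _all_pairs(nodes: tuple[str, ...]) -> list[tuple[str, str]]:
    return [(nodes[i], nodes[j]) for i in range(len(nodes)) for j in range(i + 1, len(nodes))]


def make_planted_graph(
    n_genes: int,
    n_edges: int,
    n_hubs: int = 0,
    hub_degree: int = 0,
    seed: int = 0,
    timepoint: str = "pre",
) -> PlantedGraph:
    """Plant a simple graph with ``n_hubs`` star centers and uniform fill.

    Star edges are planted first so each designated hub reaches at least
    ``hub_degree``; the remaining budget is drawn uniformly at random without
    replacement from the unoccupied pairs.  Deterministic given ``seed``.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be at least 2")
    if n_edges < 1:
        raise ValueError("n_edges must be a positive integer")
    if n_edges > pair_capacity(n_genes):
        raise ValueError(
            f"edge budget infeasible: {n_edges} edges requested but a simple "
            f"graph on {n_genes} nodes holds at most {pair_capacity(n_genes)}"
        )
    if n_hubs < 0 or hub_degree < 0:
        raise ValueError("n_hubs and hub_degree must be non-negative")
    if n_hubs > 0 and hub_degree > n_genes - 1:
        raise ValueError(f"hub_degree {hub_degree} exceeds the maximum degree {n_genes - 1}")
    if n_hubs * hub_degree > n_edges:
        raise ValueError(
            f"edge budget infeasible: {n_hubs} hubs of degree {hub_degree} "
            f"need {n_hubs * hub_degree} edges but only {n_edges} are available"
        )

    rng = np.random.default_rng(seed)
    nodes = _gene_ids(n_genes)
    edges: set[tuple[str, str]] = set()
    hubs = nodes[:n_hubs]
    for hub in hubs:
        others = [g for g in nodes if g != hub]
        # keep sampling fresh neighbors until this hub owns hub_degree new edges
        picked = 0
        order = rng.permutation(len(others))
        for idx in order:
            if picked == hub_degree:
                break
            e = tuple(sorted((hub, others[idx])))
            if e not in edges:
                edges.add(e)
                picked += 1
        if picked < hub_degree:  # pragma: no cover - guarded by budget checks
            raise ValueError(f"could not place {hub_degree} star edges for hub {hub!r}")
    free = [e for e in _all_pairs(nodes) if e not in edges]
    n_fill = n_edges - len(edges)
    fill_idx = rng.choice(len(free), size=n_fill, replace=False)
    edges.update(free[i] for i in fill_idx)
    return PlantedGraph(node_ids=nodes, edges=frozenset(edges), timepoint=timepoint)


def rewire_preserving_overlap(
    g: PlantedGraph, overlap: float, seed: int = 0, timepoint: str | None = None
) -> PlantedGraph:
    """Replace edges of ``g`` keeping ``round(overlap * |E|)`` of them.

    The retained edges are a uniform sample of the originals; replacement
    edges are drawn uniformly from pairs absent from ``g``, so the realized
    shared-edge count is exact (up to the integer rounding of the target).
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    old = sorted(g.edges)
    n_keep = round(overlap * len(old))
    keep_idx = rng.choice(len(old), size=n_keep, replace=False)
    new_edges = {old[i] for i in keep_idx}
    candidates = [e for e in _all_pairs(g.node_ids) if e not in g.edges]
    n_new = len(old) - n_keep
    if n_new > len(candidates):
        raise ValueError(
            f"replacement pairs exhausted: need {n_new} new edges but only "
            f"{len(candidates)} pairs are unused (graph too dense)"
        )
    add_idx = rng.choice(len(candidates), size=n_new, replace=False)
    new_edges.update(candidates[i] for i in add_idx)
    return PlantedGraph(
        node_ids=g.node_ids,
        edges=frozenset(new_edges),
        timepoint=g.timepoint if timepoint is None else timepoint,
    )


def graph_to_precision(g: PlantedGraph, partial_strength: float) -> np.ndarray:
    """Precision (inverse covariance) matrix realizing the planted graph.

    Off-diagonal entries are ``-partial_strength`` for planted edges and zero
    elsewhere; the uniform diagonal is set to ``max(1, 1.05 * partial_strength
    * lambda_max(A))`` (just above the adjacency spectral radius) and the
    matrix is then rescaled to unit diagonal.  This guarantees positive
    definiteness for any planted graph while keeping the realized edge
    partial correlations as strong as the graph spectrum allows; for an empty
    graph it reduces to the identity and for a single edge the off-diagonal
    is exactly ``-partial_strength``.
    """
    if not 0.0 < partial_strength < 1.0:
        raise ValueError("partial_strength must lie strictly between 0 and 1")
    p = len(g.node_ids)
    a = g.adjacency()
    if g.n_edges == 0:
        return np.eye(p)
    lam = float(np.linalg.eigvalsh(a)[-1])
    diag = max(1.0, PD_MARGIN * partial_strength * lam)
    omega = -(partial_strength / diag) * a
    np.fill_diagonal(omega, 1.0)
    min_eig = float(np.linalg.eigvalsh(omega)[0])
    if min_eig <= 0.0:  # pragma: no cover - the scaling rules this out
        raise ValueError(f"precision matrix not positive definite (min eigenvalue {min_eig:g})")
    return omega


def sample_expression(
    truth: SyntheticTruth,
    n_per_timepoint: dict[str, int],
    partial_strength: float,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Draw per-timepoint multivariate-normal expression from the planted models.

    ``noise_sd`` sets the marginal scale of the Gaussian draw (the covariance
    is ``noise_sd**2 * inv(precision)``), so the correlation structure — all
    the rank-based pipeline sees — is exactly the planted one.  The configured
    mean shift is added to ``truth.shifted_genes`` in post-treatment samples
    only.  Deterministic given ``seed``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    for tp, n in n_per_timepoint.items():
        if n < 4:
            raise ValueError(
                f"n_per_timepoint[{tp!r}] = {n} is too small; at least 4 samples "
                "are needed for a first-order partial-correlation test"
            )
    rng = np.random.default_rng(seed)
    tps = [tp for tp in TIMEPOINTS if tp in truth.graphs]
    genes = truth.graphs[tps[0]].node_ids
    blocks: list[pd.DataFrame] = []
    labels: dict[str, str] = {}
    for tp in tps:
        n = n_per_timepoint[tp]
        omega = graph_to_precision(truth.graphs[tp], partial_strength)
        sigma = np.linalg.inv(omega)
        chol = np.linalg.cholesky(sigma)
        x = noise_sd * (chol @ rng.standard_normal((len(genes), n)))
        if tp == "post" and truth.shifted_genes:
            mask = np.array([g in truth.shifted_genes for g in genes])
            x[mask, :] += truth.shift_size
        sample_ids = [f"{tp}_s{i:03d}" for i in range(n)]
        labels.update({s: tp for s in sample_ids})
        blocks.append(pd.DataFrame(x, index=list(genes), columns=sample_ids))
    values = pd.concat(blocks, axis=1)
    return ExpressionMatrix(values=values, timepoints=pd.Series(labels))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for a simulated three-timepoint experiment.

    Sample sizes default to the 58/58/60 design of the motivating study; the
    gene count, edge budget and hub layout are desk-scale stand-ins for a
    regulatory network whose true size is unknown.  ``overlap`` defaults to
    0.2, the conserved-link fraction the temporal analysis is built to detect.
    """

    n_genes: int = 100
    n_edges: int = 200
    n_hubs: int = 2
    hub_degree: int = 15
    overlap: float = 0.2
    partial_strength: float = 0.5
    frac_shifted: float = 0.5
    shift_size: float = 1.0
    noise_sd: float = 1.0
    n_per_timepoint: dict[str, int] = field(
        default_factory=lambda: {"pre": 58, "mid": 58, "post": 60}
    )
    seed: int = 0


def make_truth(cfg: SimulationConfig) -> SyntheticTruth:
    """Plant the three per-timepoint graphs and the shifted gene subset."""
    rng = np.random.default_rng(cfg.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]
    g_pre = make_planted_graph(
        cfg.n_genes, cfg.n_edges, cfg.n_hubs, cfg.hub_degree, seed=sub[0], timepoint="pre"
    )
    g_mid = rewire_preserving_overlap(g_pre, cfg.overlap, seed=sub[1], timepoint="mid")
    g_post = rewire_preserving_overlap(g_mid, cfg.overlap, seed=sub[2], timepoint="post")
    n_shift = round(cfg.frac_shifted * cfg.n_genes)
    shift_rng = np.random.default_rng(sub[3])
    shifted = shift_rng.choice(g_pre.node_ids, size=n_shift, replace=False)
    return SyntheticTruth(
        graphs={"pre": g_pre, "mid": g_mid, "post": g_post},
        overlap_requested=cfg.overlap,
        shifted_genes=frozenset(str(g) for g in shifted),
        shift_size=cfg.shift_size,
        seed=cfg.seed,
    )


def simulate_dataset(cfg: SimulationConfig) -> tuple[SyntheticTruth, ExpressionMatrix]:
    """One-call convenience: planted truth plus a sampled expression matrix."""
    truth = make_truth(cfg)
    expr = sample_expression(
        truth,
        cfg.n_per_timepoint,
        cfg.partial_strength,
        noise_sd=cfg.noise_sd,
        seed=np.random.default_rng(cfg.seed + 1).integers(0, 2**31 - 1),
    )
    return truth, expr


def write_planted_graph(g: PlantedGraph, path: str | Path) -> None:
    """Two-column tab-separated edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")


def write_truth(truth: SyntheticTruth, directory: str | Path) -> None:
    """Edge lists per timepoint plus a JSON sidecar of the parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tp, g in truth.graphs.items():
        write_planted_graph(g, directory / f"planted_{tp}.tsv")
    meta = {
        "overlap_requested": truth.overlap_requested,
        "shift_size": truth.shift_size,
        "shifted_genes": sorted(truth.shifted_genes),
        "seed": truth.seed,
        "n_genes": len(next(iter(truth.graphs.values())).node_ids),
        "n_edges": {tp: g.n_edges for tp, g in truth.graphs.items()},
    }
    with open(directory / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
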