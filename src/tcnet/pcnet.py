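"""First-order Spearman partial-correlation network inference.

A gene pair is linked at a timepoint when its zero-order Spearman rank
correlation is significant at level alpha AND its first-order partial
correlation given every other gene in the node set stays significant — the
conjunction rule of the first-order graphical screening approach.  The
conjunction removes pairs whose association is fully explained by any single
common regulator, so surviving links are direct correlations up to first
order.

Significance of a partial correlation of order q uses the t approximation
``t = rho * sqrt((n - 2 - q) / (1 - rho**2))`` with ``n - 2 - q`` degrees of
freedom, two-sided.  Since the p-value is strictly decreasing in ``|rho|`` at
fixed df, the test is applied as an exact threshold on ``|rho|``, which makes
the all-conditioners sweep a cheap vectorized minimum over correlation-matrix
slices; the pairwise loop (:func:`edge_test`) and the vectorized path
(:func:`build_network`) are algebraically identical.

A permutation null — independently shuffling each gene's values across the
timepoint's samples, destroying all inter-gene association while preserving
margins — validates that an observed edge count could not have arisen by
chance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .containers import CoexpressionNetwork, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignificanceConfig:
    """Edge-test settings: per-test level, permutation count, RNG seed."""

    alpha: float = 0.01
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")


@dataclass
class CorrelationMatrix:
    """Spearman rank correlations of the node set at one timepoint."""

    gene_ids: tuple[str, ...]
    r: np.ndarray
    n: int

    def index_of(self, gene: str) -> int:
        return self.gene_ids.index(gene)


@dataclass
class EdgeRecord:
    """Outcome of the conjunction test for one unordered gene pair."""

    is_edge: bool
    r: float
    min_abs_partial: float
    max_p: float


@dataclass
class PermutationNullResult:
    """Observed edge count against the shuffled-expression null distribution."""

    observed_edge_count: int
    null_counts: list[int]
    null_max: int = field(init=False)
    exceeds_null: bool = field(init=False)

    def __post_init__(self) -> None:
        self.null_max = max(self.null_counts)
        self.exceeds_null = self.observed_edge_count > self.null_max


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Mid-rank each row (gene) across samples."""
    return stats.rankdata(x, axis=1, method="average")


def _correlate_ranks(ranks: np.ndarray) -> np.ndarray:
    """Pearson correlation of row ranks; constant rows get zero correlation."""
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d gene(s) constant across samples; their correlations are set to 0",
            int(constant.sum()),
        )
    safe = ranks.copy()
    # give constant rows a dummy spread so corrcoef is finite, then zero them out
    safe[constant, 0] += 1.0
    r = np.corrcoef(safe)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def spearman_matrix(
    expr: ExpressionMatrix, timepoint: str, node_ids: list[str] | None = None
) -> CorrelationMatrix:
    """Spearman rank-correlation matrix of the node set at one timepoint."""
    block = expr.samples_at(timepoint)
    if node_ids is not None:
        missing = [g for g in node_ids if g not in block.index]
        if missing:
            raise KeyError(f"node ids absent from expression matrix: {missing[:5]}")
        block = block.loc[node_ids]
    n = block.shape[1]
    if n < 4:
        raise ValueError(f"timepoint {timepoint!r} has {n} samples; at least 4 are required")
    r = _correlate_ranks(_rank_rows(block.to_numpy(dtype=float)))
    return CorrelationMatrix(gene_ids=tuple(block.index), r=r, n=n)


def first_order_partial(r_ij: float, r_ik: float, r_jk: float) -> float:
    """First-order partial correlation rho_ij.k from three pairwise correlations."""
    if abs(r_ik) >= 1.0 or abs(r_jk) >= 1.0:
        raise ValueError(
            "first-order partial is undefined when a conditioning correlation is +/-1"
        )
    return (r_ij - r_ik * r_jk) / np.sqrt((1.0 - r_ik**2) * (1.0 - r_jk**2))


def partial_p_value(rho: float, n: int, order: int = 0) -> float:
    """Two-sided p for a (partial) correlation via the t approximation."""
    df = n - 2 - order
    if df < 1:
        raise ValueError(f"too few samples (n={n}) for an order-{order} partial test")
    if abs(rho) >= 1.0:
        return 0.0
    t = abs(rho) * np.sqrt(df / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(t, df))


def critical_r(alpha: float, n: int, order: int = 0) -> float:
    """|rho| threshold equivalent to the two-sided t test at level alpha."""
    df = n - 2 - order
    if df < 1:
        raise ValueError(f"too few samples (n={n}) for an order-{order} partial test")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def edge_test(i: str, j: str, corr: CorrelationMatrix, cfg: SignificanceConfig) -> EdgeRecord:
    """Conjunction test for one pair: zero-order AND every first-order partial.

    Conditioners whose correlation with either endpoint is +/-1 are skipped
    (the partial is undefined there) with a logged notice.
    """
    if len(corr.gene_ids) < 3:
        raise ValueError("the node set must contain at least 3 genes")
    if corr.n - 3 <= 0:
        raise ValueError(f"too few samples (n={corr.n}) for first-order edge testing")
    ii, jj = corr.index_of(i), corr.index_of(j)
    r_ij = float(corr.r[ii, jj])
    p0 = partial_p_value(r_ij, corr.n, order=0)
    max_p = p0
    min_abs = np.inf
    significant = p0 < cfg.alpha
    for kk, gene_k in enumerate(corr.gene_ids):
        if kk in (ii, jj):
            continue
        r_ik, r_jk = float(corr.r[ii, kk]), float(corr.r[jj, kk])
        if abs(r_ik) >= 1.0 or abs(r_jk) >= 1.0:
            logger.warning("skipping conditioner %s for pair (%s, %s)", gene_k, i, j)
            continue
        rho = first_order_partial(r_ij, r_ik, r_jk)
        if abs(rho) < min_abs:
            min_abs = abs(rho)
            max_p = max(p0, partial_p_value(rho, corr.n, order=1))
        if partial_p_value(rho, corr.n, order=1) >= cfg.alpha:
            significant = False
    return EdgeRecord(is_edge=significant, r=r_ij, min_abs_partial=float(min_abs), max_p=max_p)


def _min_abs_partial_matrix(r: np.ndarray) -> np.ndarray:
    """Entrywise minimum of |rho_ij.k| over all valid conditioners k.

    Entry (i, j) is +inf when no valid conditioner exists (then the
    first-order clause of the conjunction holds vacuously, matching the
    pairwise loop's skip semantics).
    """
    p = r.shape[0]
    min_abs = np.full((p, p), np.inf)
    for k in range(p):
        rk = r[:, k]
        margin = 1.0 - rk**2
        valid = margin > 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            pk = np.abs(r - np.outer(rk, rk)) / np.sqrt(np.outer(margin, margin))
        pk[~valid, :] = np.inf
        pk[:, ~valid] = np.inf
        pk[k, :] = np.inf
        pk[:, k] = np.inf
        np.minimum(min_abs, pk, out=min_abs)
    return min_abs


def _edge_mask(r: np.ndarray, n: int, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean adjacency of the conjunction rule plus the min-|partial| matrix."""
    r0 = critical_r(alpha, n, order=0)
    r1 = critical_r(alpha, n, order=1)
    min_abs = _min_abs_partial_matrix(r)
    mask = (np.abs(r) > r0) & (min_abs > r1)
    np.fill_diagonal(mask, False)
    return mask, min_abs


def build_network(
    expr: ExpressionMatrix,
    timepoint: str,
    node_ids: list[str],
    cfg: SignificanceConfig,
) -> CoexpressionNetwork:
    """Infer the coexpression network over ``node_ids`` at one timepoint."""
    corr = spearman_matrix(expr, timepoint, node_ids)
    if len(corr.gene_ids) < 3:
        raise ValueError("the node set must contain at least 3 genes")
    if corr.n - 3 <= 0:
        raise ValueError(f"too few samples (n={corr.n}) for first-order edge testing")
    mask, min_abs = _edge_mask(corr.r, corr.n, cfg.alpha)
    graph = nx.Graph()
    graph.add_nodes_from(corr.gene_ids)
    rows, cols = np.nonzero(np.triu(mask, k=1))
    for ii, jj in zip(rows, cols):
        r_ij = float(corr.r[ii, jj])
        m = float(min_abs[ii, jj])
        p0 = partial_p_value(r_ij, corr.n, order=0)
        p1 = partial_p_value(m, corr.n, order=1) if np.isfinite(m) else 0.0
        graph.add_edge(
            corr.gene_ids[ii],
            corr.gene_ids[jj],
            r=r_ij,
            min_abs_partial=m,
            max_p=max(p0, p1),
        )
    return CoexpressionNetwork(timepoint=timepoint, node_ids=corr.gene_ids, graph=graph)


def permutation_null(
    expr: ExpressionMatrix,
    timepoint: str,
    node_ids: list[str],
    cfg: SignificanceConfig,
) -> PermutationNullResult:
    """Edge-count null distribution from per-gene within-timepoint shuffles.

    Replicate ``r`` uses an independent RNG stream spawned from the master
    seed (``SeedSequence(seed).spawn``), so results are reproducible and the
    replicates could be farmed out in parallel without changing them.
    """
    block = expr.samples_at(timepoint)
    block = block.loc[node_ids]
    x = block.to_numpy(dtype=float)
    n = x.shape[1]
    observed = int(np.triu(_edge_mask(_correlate_ranks(_rank_rows(x)), n, cfg.alpha)[0], 1).sum())
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_permutations)
    null_counts: list[int] = []
    for child in children:
        rng = np.random.default_rng(child)
        shuffled = rng.permuted(x, axis=1)
        mask, _ = _edge_mask(_correlate_ranks(_rank_rows(shuffled)), n, cfg.alpha)
        null_counts.append(int(np.triu(mask, 1).sum()))
    return PermutationNullResult(observed_edge_count=observed, null_counts=null_counts)


def zero_order_network_size(expr: ExpressionMatrix, timepoint: str, node_ids: list[str], alpha: float) -> int:
    """Edge count of the correlation-only (no partial-correlation pruning) network."""
    corr = spearman_matrix(expr, timepoint, node_ids)
    r0 = critical_r(alpha, corr.n, order=0)
    mask = np.abs(corr.r) > r0
    np.fill_diagonal(mask, False)
    return int(np.triu(mask, 1).sum())
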