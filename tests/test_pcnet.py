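"""Partial-correlation edge testing: formula, oracle equivalence, calibration."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oracles import rank_residual_partial
from tcnet.containers import ExpressionMatrix
from tcnet import synth
from tcnet.pcnet import (
    SignificanceConfig,
    build_network,
    critical_r,
    edge_test,
    first_order_partial,
    partial_p_value,
    permutation_null,
    spearman_matrix,
    zero_order_network_size,
)


def _expr(values: np.ndarray, timepoint: str = "pre") -> ExpressionMatrix:
    genes = [f"G{i:03d}" for i in range(values.shape[0])]
    cols = [f"{timepoint}_{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=cols),
        timepoints=pd.Series({c: timepoint for c in cols}),
    )


class TestFirstOrderPartial:
    def test_direct_arithmetic(self):
        assert first_order_partial(0.8, 0.5, 0.5) == pytest.approx(0.55 / 0.75)

    def test_uncorrelated_conditioner_changes_nothing(self):
        assert first_order_partial(0.37, 0.0, 0.0) == pytest.approx(0.37)

    def test_fully_explained_pair_vanishes(self):
        assert first_order_partial(0.5 * 0.6, 0.5, 0.6) == pytest.approx(0.0)

    def test_degenerate_conditioner_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            first_order_partial(0.2, 1.0, 0.3)

    def test_matches_rank_residual_regression_oracle(self):
        """Partial from the recursion formula equals the rank-residual correlation."""
        rng = np.random.default_rng(0)
        for _ in range(40):
            x = rng.normal(size=50)
            z = rng.normal(size=50)
            y = 0.5 * z + rng.normal(size=50)
            x = x + 0.3 * z
            expr = _expr(np.vstack([x, y, z]))
            corr = spearman_matrix(expr, "pre")
            got = first_order_partial(corr.r[0, 1], corr.r[0, 2], corr.r[1, 2])
            assert got == pytest.approx(rank_residual_partial(x, y, z), abs=1e-8)


class TestSpearmanMatrix:
    def test_monotone_pair_perfectly_correlated(self):
        x = np.arange(10.0)
        expr = _expr(np.vstack([x, np.exp(x), -x, np.ones(10)]))
        corr = spearman_matrix(expr, "pre")
        assert corr.r[0, 1] == pytest.approx(1.0)
        assert corr.r[0, 2] == pytest.approx(-1.0)

    def test_constant_gene_zeroed_with_warning(self, caplog):
        x = np.arange(10.0)
        with caplog.at_level("WARNING"):
            corr = spearman_matrix(_expr(np.vstack([x, np.ones(10)])), "pre")
        assert corr.r[0, 1] == 0.0
        assert corr.r[1, 1] == 1.0
        assert "constant" in caplog.text

    def test_null_zero_order_calibration(self):
        """Disjoint independent pairs reject at the nominal alpha = 0.01 rate."""
        rng = np.random.default_rng(1)
        n, pairs = 60, 1000
        rc = critical_r(0.01, n, order=0)
        hits = 0
        for _ in range(10):
            x = rng.normal(size=(200, n))
            corr = spearman_matrix(_expr(x), "pre")
            # 100 disjoint (hence independent) pairs per batch
            hits += int(sum(abs(corr.r[2 * i, 2 * i + 1]) > rc for i in range(100)))
        rate = hits / pairs
        assert abs(rate - 0.01) < 3 * np.sqrt(0.01 * 0.99 / pairs)


class TestEdgeTest:
    def test_zero_partial_never_significant(self):
        assert partial_p_value(0.0, 60, order=1) == pytest.approx(1.0)

    def test_edge_symmetry(self, small_dataset):
        _, expr = small_dataset
        corr = spearman_matrix(expr, "pre")
        cfg = SignificanceConfig(alpha=0.01)
        for i, j in [("G00", "G05"), ("G03", "G17")]:
            a = edge_test(i, j, corr, cfg)
            b = edge_test(j, i, corr, cfg)
            assert a.is_edge == b.is_edge
            assert a.min_abs_partial == pytest.approx(b.min_abs_partial)

    def test_confounded_chain_yields_no_direct_edge(self):
        """In a planted chain i-c-j the (i, j) link is pruned by conditioning on c."""
        chain = synth.PlantedGraph(
            node_ids=("i", "c", "j", "w"),
            edges=frozenset({("c", "i"), ("c", "j")}),
        )
        truth = synth.SyntheticTruth(
            graphs={"pre": chain}, overlap_requested=0.0,
            shifted_genes=frozenset(), shift_size=0.0, seed=0,
        )
        expr = synth.sample_expression(truth, {"pre": 200}, 0.6, seed=3)
        net = build_network(expr, "pre", list(expr.gene_ids), SignificanceConfig(alpha=0.01))
        edges = net.edge_set()
        assert ("c", "i") in edges and ("c", "j") in edges
        assert ("i", "j") not in edges


class TestBuildNetwork:
    def test_vectorized_matches_pairwise_loop(self):
        """The matrix sweep and the per-pair loop give identical edge sets."""
        rng = np.random.default_rng(2)
        g = synth.make_planted_graph(15, 20, seed=4)
        truth = synth.SyntheticTruth(
            graphs={"pre": g}, overlap_requested=0.0,
            shifted_genes=frozenset(), shift_size=0.0, seed=0,
        )
        expr = synth.sample_expression(truth, {"pre": 60}, 0.6, seed=5)
        cfg = SignificanceConfig(alpha=0.05)
        net = build_network(expr, "pre", list(expr.gene_ids), cfg)
        corr = spearman_matrix(expr, "pre")
        loop_edges = set()
        genes = list(corr.gene_ids)
        for a in range(len(genes)):
            for b in range(a + 1, len(genes)):
                rec = edge_test(genes[a], genes[b], corr, cfg)
                if rec.is_edge:
                    loop_edges.add(tuple(sorted((genes[a], genes[b]))))
                    attrs = net.graph.edges[genes[a], genes[b]]
                    assert attrs["r"] == pytest.approx(rec.r, abs=1e-12)
                    assert attrs["min_abs_partial"] == pytest.approx(rec.min_abs_partial, abs=1e-12)
                    assert attrs["max_p"] == pytest.approx(rec.max_p, abs=1e-10)
        assert net.edge_set() == loop_edges

    def test_first_order_network_nested_in_zero_order(self, small_dataset):
        _, expr = small_dataset
        nodes = list(expr.gene_ids)
        cfg = SignificanceConfig(alpha=0.01)
        net = build_network(expr, "pre", nodes, cfg)
        assert net.n_links <= zero_order_network_size(expr, "pre", nodes, cfg.alpha)

    def test_planted_edges_recovered_at_strong_signal(self):
        """Sparse strong planted edges survive first-order screening.

        First-order conditioning is conservative: with the positive-definite
        cap on realized partial correlations, a documented 70% floor is the
        meaningful guarantee at these sizes.
        """
        g = synth.make_planted_graph(40, 50, seed=6)
        truth = synth.SyntheticTruth(
            graphs={"pre": g}, overlap_requested=0.0,
            shifted_genes=frozenset(), shift_size=0.0, seed=0,
        )
        expr = synth.sample_expression(truth, {"pre": 300}, 0.6, seed=7)
        net = build_network(expr, "pre", list(expr.gene_ids), SignificanceConfig(alpha=0.01))
        recovered = len(net.edge_set() & set(g.edges)) / g.n_edges
        assert recovered >= 0.70

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(8)
        expr = _expr(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="at least 4|too few"):
            build_network(expr, "pre", list(expr.gene_ids)[:5], SignificanceConfig())


class TestPermutationNull:
    def test_planted_structure_exceeds_null(self, small_dataset):
        _, expr = small_dataset
        cfg = SignificanceConfig(alpha=0.01, n_permutations=30, seed=1)
        res = permutation_null(expr, "pre", list(expr.gene_ids), cfg)
        assert res.exceeds_null
        assert res.observed_edge_count > res.null_max
        assert len(res.null_counts) == 30

    def test_null_data_does_not_exceed_null(self):
        rng = np.random.default_rng(9)
        expr = _expr(rng.normal(size=(10, 40)))
        cfg = SignificanceConfig(alpha=0.01, n_permutations=50, seed=2)
        res = permutation_null(expr, "pre", list(expr.gene_ids), cfg)
        assert not res.exceeds_null

    def test_reproducible_null_distribution(self, small_dataset):
        _, expr = small_dataset
        cfg = SignificanceConfig(alpha=0.01, n_permutations=10, seed=3)
        a = permutation_null(expr, "pre", list(expr.gene_ids), cfg)
        b = permutation_null(expr, "pre", list(expr.gene_ids), cfg)
        assert a.null_counts == b.null_counts
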