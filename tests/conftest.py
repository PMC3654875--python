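from __future__ import annotations

import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tcnet.containers import CoexpressionNetwork, ExpressionMatrix
from tcnet import synth


def net_from_edges(nodes, edges, timepoint: str = "pre") -> CoexpressionNetwork:
    """Build a bare network (no edge statistics) for topology-level tests."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return CoexpressionNetwork(timepoint=timepoint, node_ids=tuple(nodes), graph=g)


@pytest.fixture
def small_dataset() -> tuple[synth.SyntheticTruth, ExpressionMatrix]:
    """A 30-gene, 3x30-sample planted dataset shared by fast tests."""
    cfg = synth.SimulationConfig(
        n_genes=30,
        n_edges=40,
        n_hubs=1,
        hub_degree=8,
        overlap=0.5,
        partial_strength=0.5,
        frac_shifted=0.5,
        shift_size=2.0,
        n_per_timepoint={"pre": 30, "mid": 30, "post": 30},
        seed=7,
    )
    return synth.simulate_dataset(cfg)


@pytest.fixture
def expr_two_group() -> ExpressionMatrix:
    """Deterministic pre/post expression with known shifted genes."""
    rng = np.random.default_rng(11)
    genes = [f"G{i:03d}" for i in range(40)]
    pre = rng.normal(size=(40, 25))
    post = rng.normal(size=(40, 25))
    post[:10] += 2.0  # first ten genes shifted upward post-treatment
    values = pd.DataFrame(
        np.hstack([pre, post]),
        index=genes,
        columns=[f"pre_s{i}" for i in range(25)] + [f"post_s{i}" for i in range(25)],
    )
    tps = pd.Series(
        {**{f"pre_s{i}": "pre" for i in range(25)}, **{f"post_s{i}": "post" for i in range(25)}}
    )
    return ExpressionMatrix(values=values, timepoints=tps)
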