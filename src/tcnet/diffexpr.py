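"""Differential expression screen: per-gene two-group linear model with FDR control.

Each gene is fit independently with the two-group linear model (equivalent to
an unpaired pooled-variance t-test) contrasting two timepoints, and the
Benjamini-Hochberg step-up procedure converts p-values to q-values.  The
selected genes form the shared node set of the three coexpression networks.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


def fit_gene_models(
    expr: ExpressionMatrix,
    contrast: tuple[str, str] = ("pre", "post"),
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene effect, t, p, BH q, direction and selection flag.

    The effect is the second-group-minus-first-group mean difference (by
    default post minus pre, in log-expression units).  A gene with zero
    pooled variance and zero effect gets p = 1 by convention; zero pooled
    variance with a nonzero effect gets p = 0 (infinite t).
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must lie strictly between 0 and 1")
    group_a, group_b = contrast
    xa = expr.samples_at(group_a).to_numpy(dtype=float)
    xb = expr.samples_at(group_b).to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(
            f"contrast {contrast} needs at least 2 samples per group; got {na} and {nb}"
        )
    effect = xb.mean(axis=1) - xa.mean(axis=1)
    ssa = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((xb - xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = na + nb - 2
    pooled_var = (ssa + ssb) / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))

    t_stat = np.zeros_like(effect)
    p_value = np.ones_like(effect)
    regular = se > 0
    t_stat[regular] = effect[regular] / se[regular]
    p_value[regular] = 2.0 * stats.t.sf(np.abs(t_stat[regular]), df)
    degenerate = ~regular
    if degenerate.any():
        exploded = degenerate & (effect != 0)
        t_stat[exploded] = np.sign(effect[exploded]) * np.inf
        p_value[exploded] = 0.0
        flat = degenerate & (effect == 0)
        p_value[flat] = 1.0  # no variance, no effect: nothing to test
        logger.warning(
            "%d gene(s) with zero pooled variance in contrast %s", int(degenerate.sum()), contrast
        )

    _, q_value, _, _ = multipletests(p_value, method="fdr_bh")
    direction = np.where(effect > 0, "up", "down")
    selected = q_value <= fdr_threshold
    return pd.DataFrame(
        {
            "effect": effect,
            "t_stat": t_stat,
            "p_value": p_value,
            "q_value": q_value,
            "direction": direction,
            "selected": selected,
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )


def select_node_set(table: pd.DataFrame) -> list[str]:
    """Selected genes in stable lexicographic order: the shared network node set."""
    chosen = sorted(table.index[table["selected"]])
    if not chosen:
        raise ValueError(
            "no gene passed the FDR threshold; relax the threshold or supply "
            "an explicit node list"
        )
    return chosen
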