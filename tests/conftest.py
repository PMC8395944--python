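"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive expected values by enumeration or
closed form, independent of the package's implementation paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from immunorewire.qc_preprocess import ExprMatrix
from immunorewire.synthetic_data import CountMatrix


# ---------------------------------------------------------------- oracles


def brute_force_ks_d(x, y) -> float:
    """Supremum |F_x - F_y| evaluated point-by-point on the pooled sample."""
    x = list(x)
    y = list(y)
    best = 0.0
    for t in x + y:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def brute_force_qc_survivors(counts, gene_ids, min_f, max_f, max_mito, prefix="mt-"):
    """Enumerate cells passing the strict QC bounds, one cell at a time."""
    survivors = []
    for i, row in enumerate(counts):
        n_feat = sum(1 for v in row if v > 0)
        total = sum(row)
        mito = sum(v for v, g in zip(row, gene_ids) if g.lower().startswith(prefix))
        pct = 100.0 * mito / total if total > 0 else 0.0
        if min_f < n_feat < max_f and pct < max_mito:
            survivors.append(i)
    return survivors


def brute_force_bh(p):
    """Benjamini-Hochberg by the textbook step-up definition."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        adj[i] = val
        prev = val
    return adj


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 cells x 3 genes, both conditions, with a planted type per cell."""
    counts = np.array(
        [
            [5, 0, 2],
            [0, 3, 1],
            [4, 1, 0],
            [1, 2, 6],
        ]
    )
    return CountMatrix(
        counts=counts,
        cell_ids=["c0", "c1", "c2", "c3"],
        gene_ids=["GeneA", "GeneB", "GeneC"],
        condition=["control", "control", "treated", "treated"],
        true_type=["T1", "T2", "T1", "T2"],
    )


def make_expr(values, conditions, labels=None, gene_ids=None, prefix="cell"):
    """Build an ExprMatrix (and optional label map) from a dense array."""
    values = np.asarray(values, dtype=float)
    cell_ids = [f"{prefix}{i}" for i in range(values.shape[0])]
    gene_ids = gene_ids or [f"g{j}" for j in range(values.shape[1])]
    expr = ExprMatrix(
        values=values,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        condition=list(conditions),
    )
    if labels is None:
        return expr
    return expr, dict(zip(cell_ids, labels))
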