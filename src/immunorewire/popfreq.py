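"""Two-sample ECDF comparison and cytotoxic-marker coexpression networks.

``ks_two_sample`` computes the exact supremum distance between two step
ECDFs (evaluated on the pooled sample points, ties included) and the
asymptotic Kolmogorov tail probability with the standard small-sample
correction in the effective sample size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import label_propagation_communities
from .qc_preprocess import ExprMatrix

__all__ = [
    "ECDFComparison",
    "CoexpressionNetwork",
    "ks_two_sample",
    "ecdf_compare",
    "coexpression_network",
]


@dataclass
class ECDFComparison:
    cell_type: str
    marker_set: tuple[str, ...]
    n_control: int
    n_treated: int
    D: float
    p: float
    direction: int  # sign of (treated mean - control mean)


@dataclass
class CoexpressionNetwork:
    cell_type: str
    condition: str
    graph: nx.Graph  # nodes = marker genes, edges carry Pearson r
    communities: dict[str, int]


def _kolmogorov_sf(lam: float, tol: float = 1e-12) -> float:
    """Two-sided Kolmogorov tail: 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lam^2)."""
    if lam <= 0:
        return 1.0
    total = 0.0
    for k in range(1, 200):
        term = math.exp(-2.0 * k * k * lam * lam)
        total += term if k % 2 == 1 else -term
        if term < tol:
            break
    return min(max(2.0 * total, np.nextafter(0.0, 1.0)), 1.0)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Exact-sup two-sample KS statistic and asymptotic p-value.

    D is the supremum of |F_x - F_y| over the pooled sample points (exact for
    step ECDFs, ties handled).  p uses lambda = (sqrt(n_e) + 0.12 +
    0.11/sqrt(n_e)) * D with n_e = nx*ny/(nx+ny), clipped to (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    xs = np.sort(x)
    ys = np.sort(y)
    grid = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, grid, side="right") / xs.size
    fy = np.searchsorted(ys, grid, side="right") / ys.size
    d = float(np.max(np.abs(fx - fy)))
    n_e = xs.size * ys.size / (xs.size + ys.size)
    lam = (math.sqrt(n_e) + 0.12 + 0.11 / math.sqrt(n_e)) * d
    return d, _kolmogorov_sf(lam)


def ecdf_compare(
    expr: ExprMatrix,
    labels: dict[str, str],
    cell_type: str,
    marker_set: list[str],
    min_cells: int = 5,
) -> ECDFComparison:
    """KS comparison of per-cell mean marker expression between conditions.

    The per-cell statistic is the mean of the (already log1p) expression
    values over ``marker_set``; the two condition arms' ECDFs are compared.
    """
    if not marker_set:
        raise ValueError("marker_set must be nonempty")
    gidx = [expr.gene_ids.index(g) for g in marker_set if g in expr.gene_ids]
    if not gidx:
        raise ValueError("no marker gene present in the matrix")
    if len(gidx) < len(marker_set):
        missing = [g for g in marker_set if g not in expr.gene_ids]
        warnings.warn(f"markers not in matrix: {', '.join(missing)}", stacklevel=2)

    per_cell = expr.values[:, gidx].mean(axis=1)
    lab = np.array([labels.get(c) for c in expr.cell_ids], dtype=object)
    cond = np.asarray(expr.condition)
    arms = {}
    for c in ("control", "treated"):
        vals = per_cell[(lab == cell_type) & (cond == c)]
        if vals.size < min_cells:
            raise ValueError(
                f"cell type {cell_type!r} has {vals.size} cells in {c!r} "
                f"(need >= {min_cells})"
            )
        arms[c] = vals
    d, p = ks_two_sample(arms["control"], arms["treated"])
    direction = int(np.sign(arms["treated"].mean() - arms["control"].mean()))
    return ECDFComparison(
        cell_type=cell_type,
        marker_set=tuple(marker_set),
        n_control=int(arms["control"].size),
        n_treated=int(arms["treated"].size),
        D=d,
        p=p,
        direction=direction,
    )


def coexpression_network(
    expr: ExprMatrix,
    labels: dict[str, str],
    cell_type: str,
    markers: list[str],
    condition: str,
    r_min: float = 0.3,
    seed: int = 0,
) -> CoexpressionNetwork:
    """Pearson coexpression graph over markers in one cell type and condition.

    Edges require |r| >= r_min; zero-variance markers are excluded with a
    warning; communities come from label propagation on the thresholded graph.
    """
    if len(markers) < 3:
        raise ValueError("need at least 3 markers")
    lab = np.array([labels.get(c) for c in expr.cell_ids], dtype=object)
    cond = np.asarray(expr.condition)
    mask = (lab == cell_type) & (cond == condition)
    if mask.sum() < 10:
        raise ValueError(
            f"only {int(mask.sum())} cells of {cell_type!r} in {condition!r} (need >= 10)"
        )
    present = [g for g in markers if g in expr.gene_ids]
    if len(present) < len(markers):
        missing = [g for g in markers if g not in expr.gene_ids]
        warnings.warn(f"markers not in matrix: {', '.join(missing)}", stacklevel=2)
    sub = expr.values[np.ix_(mask, [expr.gene_ids.index(g) for g in present])]

    variances = sub.var(axis=0)
    keep = variances > 0
    dropped = [g for g, k in zip(present, keep) if not k]
    if dropped:
        warnings.warn(f"zero-variance markers excluded: {', '.join(dropped)}", stacklevel=2)
    genes = [g for g, k in zip(present, keep) if k]
    sub = sub[:, keep]

    g = nx.Graph()
    g.add_nodes_from(genes)
    if len(genes) >= 2:
        r = np.corrcoef(sub, rowvar=False)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if abs(r[i, j]) >= r_min:
                    g.add_edge(genes[i], genes[j], weight=float(abs(r[i, j])), r=float(r[i, j]))
    communities = label_propagation_communities(g, seed=seed)
    return CoexpressionNetwork(
        cell_type=cell_type, condition=condition, graph=g, communities=communities
    )


def ecdf_table(comparisons: list[ECDFComparison]) -> pd.DataFrame:
    rows = [
        (
            c.cell_type,
            ",".join(c.marker_set),
            c.n_control,
            c.n_treated,
            c.D,
            c.p,
            c.direction,
        )
        for c in comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_type", "markers", "n_ctrl", "n_trt", "D", "p", "direction"],
    )
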