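"""Differential expression between conditions with detection-fraction and
fold-change gates.

The test statistic is a two-sided Wilcoxon rank-sum (normal approximation
with tie correction) on log1p values — a stand-in for hurdle-model testing;
the detection (pct) and log-fold-change gates and their 0.25 defaults are the
contract reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc_preprocess import ExprMatrix

__all__ = ["DEResult", "de_test", "bh_adjust"]


@dataclass
class DEResult:
    gene: str
    cell_type: str
    logfc: float  # natural-log fold change, treated vs control
    pct_1: float  # detection fraction, treated
    pct_2: float  # detection fraction, control
    p: float
    p_adj: float


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p, tie-corrected normal approximation."""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def de_test(
    expr: ExprMatrix,
    labels: dict[str, str],
    cell_type: str,
    min_pct: float = 0.25,
    min_logfc: float = 0.25,
    genes: list[str] | None = None,
) -> list[DEResult]:
    """Treated-vs-control DE within one cell type.

    * ``pct_1``/``pct_2`` — fraction of treated/control cells with value > 0.
    * gate: ``max(pct_1, pct_2) >= min_pct`` and ``|logFC| >= min_logfc`` where
      ``logFC = ln(mean(expm1(treated)) + 1) - ln(mean(expm1(control)) + 1)``.
    * p from the rank-sum test on the gated genes; BH adjustment within the
      cell type (over the gated genes).

    Set both gates to 0 to test every gene.
    """
    lab = np.array([labels.get(c) for c in expr.cell_ids], dtype=object)
    cond = np.asarray(expr.condition)
    arm = {}
    for c in ("control", "treated"):
        idx = np.flatnonzero((lab == cell_type) & (cond == c))
        if idx.size < 3:
            raise ValueError(
                f"cell type {cell_type!r} has {idx.size} cells in {c!r} (need >= 3)"
            )
        arm[c] = expr.values[idx]

    gene_ids = expr.gene_ids
    if genes is not None:
        cols = [gene_ids.index(g) for g in genes if g in gene_ids]
        names = [g for g in genes if g in gene_ids]
    else:
        cols = list(range(len(gene_ids)))
        names = list(gene_ids)

    trt = arm["treated"][:, cols]
    ctl = arm["control"][:, cols]
    pct1 = (trt > 0).mean(axis=0)
    pct2 = (ctl > 0).mean(axis=0)
    logfc = np.log(np.expm1(trt).mean(axis=0) + 1.0) - np.log(
        np.expm1(ctl).mean(axis=0) + 1.0
    )
    gate = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(logfc) >= min_logfc)

    kept = np.flatnonzero(gate)
    pvals = np.array([_ranksum_p(trt[:, j], ctl[:, j]) for j in kept])
    padj = bh_adjust(pvals)

    results = [
        DEResult(
            gene=names[j],
            cell_type=cell_type,
            logfc=float(logfc[j]),
            pct_1=float(pct1[j]),
            pct_2=float(pct2[j]),
            p=float(pvals[i]),
            p_adj=float(padj[i]),
        )
        for i, j in enumerate(kept)
    ]
    results.sort(key=lambda r: (r.p, r.gene))
    return results


def de_table(results: list[DEResult]) -> pd.DataFrame:
    rows = [
        (r.cell_type, r.gene, r.logfc, r.pct_1, r.pct_2, r.p, r.p_adj)
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["cell_type", "gene", "logFC", "pct_1", "pct_2", "p", "p_adj"]
    )
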