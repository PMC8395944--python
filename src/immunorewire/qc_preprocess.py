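"""QC filtering and normalization.

Cells are retained when ``min_features < detected genes < max_features`` (both
bounds strict) and the mitochondrial fraction of counts, expressed in percent,
is strictly below ``max_mito_pct``.  Retained counts are library-size scaled
and log1p-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import CountMatrix

__all__ = ["QCParams", "ExprMatrix", "qc_filter", "normalize_log1p", "knn_smooth"]


@dataclass(frozen=True)
class QCParams:
    min_features: int = 200  # exclusive lower bound
    max_features: int = 4000  # exclusive upper bound
    max_mito_pct: float = 3.0  # exclusive upper bound, percent
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not (0 <= self.min_features < self.max_features):
            raise ValueError("need 0 <= min_features < max_features")
        if not (0 <= self.max_mito_pct <= 100):
            raise ValueError("max_mito_pct must be within [0, 100]")


@dataclass
class ExprMatrix:
    """Normalized log1p expression values (cells x genes) with cell metadata."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    condition: list[str]
    true_type: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


class AllCellsFilteredError(RuntimeError):
    """Raised when QC leaves no cells rather than returning an empty matrix."""


def qc_filter(m: CountMatrix, params: QCParams | None = None) -> CountMatrix:
    """Drop cells violating the feature-count or mitochondrial-percent bounds.

    Genes are never removed; cell order is preserved.  All three bounds are
    strict inequalities: a cell with exactly ``min_features`` detected genes or
    exactly ``max_mito_pct`` percent mitochondrial counts is removed.
    """
    params = params if params is not None else QCParams()
    n_features = (m.counts > 0).sum(axis=1)
    totals = m.counts.sum(axis=1)
    mito_cols = [
        i for i, g in enumerate(m.gene_ids) if g.lower().startswith(params.mito_prefix.lower())
    ]
    if mito_cols:
        mito_counts = m.counts[:, mito_cols].sum(axis=1)
    else:
        mito_counts = np.zeros(m.n_cells, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito_counts / totals, 0.0)

    keep = (
        (n_features > params.min_features)
        & (n_features < params.max_features)
        & (mito_pct < params.max_mito_pct)
    )
    if not keep.any():
        raise AllCellsFilteredError(
            "QC removed every cell "
            f"(min_features={params.min_features}, max_features={params.max_features}, "
            f"max_mito_pct={params.max_mito_pct})"
        )
    idx = np.flatnonzero(keep)
    return CountMatrix(
        counts=m.counts[idx],
        cell_ids=[m.cell_ids[i] for i in idx],
        gene_ids=list(m.gene_ids),
        condition=[m.condition[i] for i in idx],
        true_type=[m.true_type[i] for i in idx] if m.true_type is not None else None,
    )


def normalize_log1p(m: CountMatrix, scale: float = 1e4) -> ExprMatrix:
    """log1p of library-size-scaled counts: ln(1 + scale * count / cell_total)."""
    if m.n_cells == 0:
        raise ValueError("empty matrix")
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = m.counts.sum(axis=1).astype(float)
    if (totals == 0).any():
        zero = [m.cell_ids[i] for i in np.flatnonzero(totals == 0)][:5]
        raise ValueError(f"cells with zero total counts reached normalization: {zero}")
    values = np.log1p(scale * m.counts / totals[:, None])
    return ExprMatrix(
        values=values,
        cell_ids=list(m.cell_ids),
        gene_ids=list(m.gene_ids),
        condition=list(m.condition),
        true_type=list(m.true_type) if m.true_type is not None else None,
    )


def knn_smooth(expr: ExprMatrix, k: int = 15, n_pcs: int = 20) -> ExprMatrix:
    """Optional kNN-average smoothing (each cell averaged with its k nearest
    neighbors in PCA space).

    This is a simple stand-in for diffusion-based imputation and is NOT
    equivalent to it; default pipelines leave it off.
    """
    from sklearn.neighbors import NearestNeighbors

    if k < 1:
        raise ValueError("k must be >= 1")
    if expr.n_cells <= k:
        raise ValueError("k must be smaller than the number of cells")
    centered = expr.values - expr.values.mean(axis=0)
    n_pcs = min(n_pcs, min(centered.shape) - 1)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    smoothed = expr.values[idx].mean(axis=1)
    return ExprMatrix(
        values=smoothed,
        cell_ids=list(expr.cell_ids),
        gene_ids=list(expr.gene_ids),
        condition=list(expr.condition),
        true_type=list(expr.true_type) if expr.true_type is not None else None,
    )
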