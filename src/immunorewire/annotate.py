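"""Marker-panel annotation of clusters and marker-positive cell fractions.

A :class:`MarkerPanel` maps (cell type, gene) to a sign: +1 for markers
expected high in that type, -1 for markers expected low, 0 (absent) for
uninformative genes.  Clusters are labeled by the type whose sign-weighted
mean of across-cluster z-scores is maximal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc_preprocess import ExprMatrix

__all__ = [
    "MarkerPanel",
    "AnnotationResult",
    "default_marker_panel",
    "annotate_clusters",
    "marker_positive_fraction",
    "cell_labels_from_clusters",
]

UNASSIGNED = "unassigned"

# Built-in panel: murine tumor-infiltrating immune populations.
# Each entry: type -> {gene: sign}.
_DEFAULT_PANEL: dict[str, dict[str, int]] = {
    "M2_noncommitted_NC": {
        "Cd68": 1, "Adgre1": 1, "Cx3cr1": 1, "Itgax": 1, "Cxcl16": 1,
        "Ccr2": -1, "Sell": -1,
    },
    "M2_partial": {"Cd68": 1, "Vegfa": 1, "Arg1": 1, "Itgax": -1, "Cxcl16": -1},
    "M2": {"H2-Aa": 1, "H2-Ab1": 1, "Cx3cr1": 1, "Adgre1": 1, "Ccl5": 1, "Cxcl16": 1},
    "Not_committed": {"Cd68": 1},
    "M1_partial_TAM": {
        "Arg2": 1, "Il1b": 1, "Cd80": 1, "Csf2rb": 1, "Sell": 1,
        "H2-Aa": -1, "H2-Ab1": -1,
    },
    "M1_committed": {
        "Csf2rb": 1, "Cd80": 1, "H2-Aa": 1, "H2-Ab1": 1, "Itgax": 1,
        "Cd86": 1, "Il1b": 1,
    },
    "M1_polarized": {"Cd80": 1, "Csf2rb": 1, "Cd86": 1, "Ccl5": 1, "Cxcl16": 1},
    "M2_committed_NC": {"Cx3cr1": 1, "Adgre1": 1, "Tlr8": 1, "Cd86": -1},
    "Classical_monocyte": {"Ly6c1": 1},
    "CD8_T": {"Cd3e": 1, "Cd8a": 1},
    "CD4_T": {"Cd3e": 1, "Cd4": 1},
    "NK": {"Ncr1": 1, "Cd3e": -1},
    "T_M": {"Cd3e": 1, "Cd68": 1, "Tnf": 1, "Lamp1": 1, "Ccr5": 1, "Il1b": 1},
    "DC": {"Itgax": 1, "H2-Aa": 1, "H2-Ab1": 1},
}

# Myeloid types used for composition defaults elsewhere.
MYELOID_TYPES = (
    "M2_noncommitted_NC", "M2_partial", "M2", "Not_committed", "M1_partial_TAM",
    "M1_committed", "M1_polarized", "M2_committed_NC", "Classical_monocyte", "DC",
)


@dataclass(frozen=True)
class MarkerPanel:
    """Cell-type x gene sign table with values in {+1, -1, 0 (absent)}."""

    signs: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        for ctype, genes in self.signs.items():
            nonzero = [g for g, s in genes.items() if s != 0]
            if not nonzero:
                raise ValueError(f"cell type {ctype!r} has no nonzero marker signs")
            for g, s in genes.items():
                if s not in (-1, 0, 1):
                    raise ValueError(f"invalid sign {s!r} for ({ctype!r}, {g!r})")

    @property
    def cell_types(self) -> list[str]:
        return list(self.signs)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for table in self.signs.values():
            for g in table:
                seen.setdefault(g, None)
        return list(seen)

    def sign(self, cell_type: str, gene: str) -> int:
        return self.signs.get(cell_type, {}).get(gene, 0)

    def to_frame(self) -> pd.DataFrame:
        """Long-form (cell_type, gene, sign) table of the nonzero entries."""
        rows = [
            (t, g, s)
            for t, table in self.signs.items()
            for g, s in table.items()
            if s != 0
        ]
        return pd.DataFrame(rows, columns=["cell_type", "gene", "sign"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MarkerPanel":
        required = {"cell_type", "gene", "sign"}
        if not required.issubset(frame.columns):
            raise ValueError(f"panel table needs columns {sorted(required)}")
        signs: dict[str, dict[str, int]] = {}
        for row in frame.itertuples(index=False):
            signs.setdefault(str(row.cell_type), {})[str(row.gene)] = int(row.sign)
        return cls(signs)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MarkerPanel":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_marker_panel() -> MarkerPanel:
    """Built-in murine TIL panel (10 myeloid + 4 lymphoid populations)."""
    return MarkerPanel({t: dict(g) for t, g in _DEFAULT_PANEL.items()})


@dataclass
class AnnotationResult:
    """Per-cluster label, full score vector, and winning margin."""

    labels: dict[int, str]
    scores: pd.DataFrame  # clusters x cell types
    margins: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, self.labels[c], self.margins.get(c, np.nan))
            for c in sorted(self.labels)
        ]
        return pd.DataFrame(rows, columns=["cluster", "label", "margin"])


def _resolve_panel_genes(panel: MarkerPanel, gene_ids: list[str]) -> dict[str, int]:
    """Map resolvable panel genes to matrix column indices; warn on misses."""
    index = {g: i for i, g in enumerate(gene_ids)}
    resolved: dict[str, int] = {}
    missing: list[str] = []
    for g in panel.genes:
        if g in index:
            resolved[g] = index[g]
        else:
            missing.append(g)
    if missing:
        warnings.warn(
            f"{len(missing)} panel gene(s) not in matrix: {', '.join(sorted(missing))}",
            stacklevel=3,
        )
    return resolved


def annotate_clusters(
    expr: ExprMatrix,
    clusters: dict[str, int],
    panel: MarkerPanel | None = None,
    min_cells: int = 3,
) -> AnnotationResult:
    """Label each cluster by its best-matching panel cell type.

    For every panel gene the cluster-mean expression is z-scored across
    clusters; ``score(c, t)`` is the mean of ``sign(t, g) * z(c, g)`` over the
    nonzero-sign genes of ``t``.  The label is the argmax (alphabetical
    tie-break); ``margin`` is best minus second-best score.  Clusters with
    fewer than ``min_cells`` cells are labeled ``"unassigned"``.
    """
    panel = panel if panel is not None else default_marker_panel()
    gene_idx = _resolve_panel_genes(panel, expr.gene_ids)
    for ctype in panel.cell_types:
        usable = [g for g, s in panel.signs[ctype].items() if s != 0 and g in gene_idx]
        if not usable:
            raise ValueError(
                f"cell type {ctype!r} has no resolvable marker genes in the matrix"
            )

    cluster_ids = sorted(set(clusters.values()))
    cell_pos = {c: i for i, c in enumerate(expr.cell_ids)}
    members: dict[int, list[int]] = {c: [] for c in cluster_ids}
    for cell, cl in clusters.items():
        members[cl].append(cell_pos[cell])

    genes = list(gene_idx)
    cols = [gene_idx[g] for g in genes]
    # cluster-mean expression for panel genes
    means = np.zeros((len(cluster_ids), len(genes)))
    small: set[int] = set()
    for r, cl in enumerate(cluster_ids):
        idx = members[cl]
        if len(idx) < min_cells:
            small.add(cl)
        if idx:
            means[r] = expr.values[np.asarray(idx)][:, cols].mean(axis=0)

    if len(cluster_ids) >= 2:
        mu = means.mean(axis=0)
        sd = means.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (means - mu) / sd, 0.0)
    else:
        z = means - means.mean(axis=0)  # raw centered means

    types = panel.cell_types
    score = np.zeros((len(cluster_ids), len(types)))
    gpos = {g: j for j, g in enumerate(genes)}
    for t_i, ctype in enumerate(types):
        entries = [
            (gpos[g], s)
            for g, s in panel.signs[ctype].items()
            if s != 0 and g in gpos
        ]
        sgn = np.array([s for _, s in entries], dtype=float)
        col = np.array([j for j, _ in entries], dtype=int)
        score[:, t_i] = (z[:, col] * sgn).sum(axis=1) / len(entries)

    scores = pd.DataFrame(score, index=cluster_ids, columns=types)
    labels: dict[int, str] = {}
    margins: dict[int, float] = {}
    for r, cl in enumerate(cluster_ids):
        if cl in small:
            warnings.warn(f"cluster {cl} has < {min_cells} cells; unassigned", stacklevel=2)
            labels[cl] = UNASSIGNED
            margins[cl] = 0.0
            continue
        row = score[r]
        best = row.max()
        winners = sorted(types[i] for i in np.flatnonzero(row == best))
        labels[cl] = winners[0]
        if len(types) == 1:
            margins[cl] = 0.0
        else:
            second = np.partition(row, -2)[-2]
            margins[cl] = float(best - second)
    return AnnotationResult(labels=labels, scores=scores, margins=margins)


def cell_labels_from_clusters(
    clusters: dict[str, int], annotation: AnnotationResult
) -> dict[str, str]:
    """Propagate cluster labels to cells (every cell inherits its cluster's label)."""
    return {cell: annotation.labels[cl] for cell, cl in clusters.items()}


def marker_positive_fraction(
    expr: ExprMatrix,
    labels: dict[str, str],
    gene_set: list[str],
    threshold: float,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Fraction of cells per (type, condition) whose mean expression over
    ``gene_set`` exceeds ``threshold``.

    A type absent from one condition yields ``NaN`` for that condition (flagged
    via the ``defined`` column), never a silent 0.
    """
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    gidx = [expr.gene_ids.index(g) for g in gene_set if g in expr.gene_ids]
    missing = [g for g in gene_set if g not in expr.gene_ids]
    if missing:
        warnings.warn(f"genes not in matrix: {', '.join(missing)}", stacklevel=2)
    if not gidx:
        raise ValueError("no gene in gene_set is present in the matrix")

    per_cell = expr.values[:, gidx].mean(axis=1)
    lab = np.array([labels.get(c, UNASSIGNED) for c in expr.cell_ids])
    cond = np.asarray(expr.condition)
    types = cell_types if cell_types is not None else sorted(set(lab) - {UNASSIGNED})

    rows = []
    for t in types:
        for c in ("control", "treated"):
            mask = (lab == t) & (cond == c)
            n = int(mask.sum())
            if n == 0:
                rows.append((t, c, n, np.nan, False))
            else:
                frac = float((per_cell[mask] > threshold).mean())
                rows.append((t, c, n, frac, True))
    return pd.DataFrame(
        rows, columns=["cell_type", "condition", "n_cells", "fraction", "defined"]
    )
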