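"""Ligand-receptor communication scoring and LR-network communities.

For every ordered (sender, receiver) cell-type pair and LR pair (l, q), the
communication score in a condition is the product of the mean expression of l
in the sender's cells and the mean expression of q in the receiver's cells;
the treated-minus-control difference infers rewired signaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .clustering import label_propagation_communities
from .diffexpr import DEResult
from .qc_preprocess import ExprMatrix

__all__ = [
    "LRPairTable",
    "LRScoreTable",
    "LRNetwork",
    "default_lr_pairs",
    "select_ligands",
    "lr_score",
    "lr_delta_heatmap",
    "lr_network_communities",
]

# Bundled demo table: murine chemokine/cytokine ligand-receptor pairs.
_DEFAULT_PAIRS: list[tuple[str, str]] = [
    ("Ccl2", "Ccr2"), ("Ccl7", "Ccr2"), ("Ccl8", "Ccr2"), ("Ccl12", "Ccr2"),
    ("Ccl3", "Ccr5"), ("Ccl4", "Ccr5"), ("Ccl5", "Ccr5"), ("Ccl5", "Ccr1"),
    ("Ccl3", "Ccr1"), ("Ccl8", "Ccr5"),
    ("Cxcl12", "Cxcr4"), ("Cd74", "Cxcr4"), ("Cxcl13", "Cxcr5"),
    ("Ccl21a", "Ccr7"), ("Ccl19", "Ccr7"), ("Ccl22", "Ccr4"), ("Ccl17", "Ccr4"),
    ("Cxcl9", "Cxcr3"), ("Cxcl10", "Cxcr3"), ("Cxcl11", "Cxcr3"),
    ("Cxcl16", "Cxcr6"), ("Cx3cl1", "Cx3cr1"),
    ("Ifng", "Ifngr1"), ("Ifng", "Ifngr2"),
    ("Il1b", "Il1r1"), ("Il1a", "Il1r1"), ("Il6", "Il6ra"), ("Il10", "Il10ra"),
    ("Il12a", "Il12rb1"), ("Il15", "Il15ra"), ("Il18", "Il18r1"),
    ("Tnf", "Tnfrsf1a"), ("Tnf", "Tnfrsf1b"), ("Tgfb1", "Tgfbr1"),
    ("Csf1", "Csf1r"), ("Csf2", "Csf2ra"), ("Csf2", "Csf2rb"),
    ("Flt3l", "Flt3"), ("Kitl", "Kit"), ("Vegfa", "Flt1"),
]


@dataclass
class LRPairTable:
    """Directed ligand -> receptor gene pairs, optionally tagged with the
    sender cell types in which the ligand qualified."""

    pairs: list[tuple[str, str]]
    sender_types: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValueError("ligand and receptor gene names must be non-empty")
            if (lig, rec) in seen:
                raise ValueError(f"duplicate pair ({lig!r}, {rec!r})")
            seen.add((lig, rec))

    @property
    def ligands(self) -> list[str]:
        out: dict[str, None] = {}
        for lig, _ in self.pairs:
            out.setdefault(lig, None)
        return list(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["ligand", "receptor"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LRPairTable":
        if not {"ligand", "receptor"}.issubset(frame.columns):
            raise ValueError("pair table needs 'ligand' and 'receptor' columns")
        return cls([(str(r.ligand), str(r.receptor)) for r in frame.itertuples(index=False)])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "LRPairTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_lr_pairs() -> LRPairTable:
    """Bundled ~40-pair murine chemokine/cytokine demo table."""
    return LRPairTable(list(_DEFAULT_PAIRS))


@dataclass
class LRScoreTable:
    """Per (sender, receiver, ligand, receptor) condition scores and delta."""

    frame: pd.DataFrame  # columns: sender, receiver, ligand, receptor,
    #          score_control, score_treated, delta
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class LRNetwork:
    graph: nx.Graph  # nodes = genes, edges = LR pairs
    communities: dict[str, int]

    @property
    def n_communities(self) -> int:
        return len(set(self.communities.values())) if self.communities else 0


def select_ligands(
    de: list[DEResult], pairs: LRPairTable, alpha: float = 0.05
) -> LRPairTable:
    """Keep pairs whose ligand is differentially expressed (p < alpha) in at
    least one sender cell type; records qualifying sender types per ligand."""
    qualifying: dict[str, list[str]] = {}
    for r in de:
        if r.p < alpha:
            types = qualifying.setdefault(r.gene, [])
            if r.cell_type not in types:
                types.append(r.cell_type)
    kept = [(lig, rec) for lig, rec in pairs.pairs if lig in qualifying]
    if not kept:
        warnings.warn("no ligand passed the DE cutoff; empty pair table", stacklevel=2)
    senders = {lig: qualifying[lig] for lig, _ in kept}
    return LRPairTable(kept, sender_types=senders)


def lr_score(
    expr: ExprMatrix, labels: dict[str, str], pairs: LRPairTable
) -> LRScoreTable:
    """Product-of-means communication scores for all ordered type pairs.

    ``score_c(sender, receiver, l, q) = mean expr of l over the sender's cells
    in condition c  x  mean expr of q over the receiver's cells in c``;
    ``delta = score_treated - score_control``.  Autocrine (sender == receiver)
    pairs are included.  Pairs whose ligand or receptor is absent from the
    matrix are skipped with a warning; a cell type absent from a condition
    yields NaN scores for rows involving it (flagged, never 0).
    """
    lab = np.array([labels.get(c) for c in expr.cell_ids], dtype=object)
    cond = np.asarray(expr.condition)
    types = sorted({t for t in lab if t is not None and t != "unassigned"})
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}

    usable, skipped = [], []
    for lig, rec in pairs.pairs:
        (usable if lig in gidx and rec in gidx else skipped).append((lig, rec))
    if skipped:
        warnings.warn(
            f"{len(skipped)} pair(s) skipped (gene absent): "
            + ", ".join(f"{l}->{r}" for l, r in skipped),
            stacklevel=2,
        )

    # mean expression per (type, condition) for every needed gene
    genes_needed = sorted({g for pr in usable for g in pr})
    cols = [gidx[g] for g in genes_needed]
    gpos = {g: j for j, g in enumerate(genes_needed)}
    means: dict[tuple[str, str], np.ndarray | None] = {}
    for t in types:
        for c in ("control", "treated"):
            mask = (lab == t) & (cond == c)
            if mask.any():
                means[(t, c)] = expr.values[np.ix_(mask, cols)].mean(axis=0)
            else:
                means[(t, c)] = None
                warnings.warn(f"type {t!r} absent in condition {c!r}; scores NaN", stacklevel=2)

    rows = []
    for sender in types:
        for receiver in types:
            for lig, rec in usable:
                scores = {}
                for c in ("control", "treated"):
                    ms, mr = means[(sender, c)], means[(receiver, c)]
                    if ms is None or mr is None:
                        scores[c] = np.nan
                    else:
                        scores[c] = float(ms[gpos[lig]] * mr[gpos[rec]])
                rows.append(
                    (
                        sender,
                        receiver,
                        lig,
                        rec,
                        scores["control"],
                        scores["treated"],
                        scores["treated"] - scores["control"],
                    )
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "sender", "receiver", "ligand", "receptor",
            "score_control", "score_treated", "delta",
        ],
    )
    return LRScoreTable(frame=frame, skipped_pairs=skipped)


def lr_delta_heatmap(table: LRScoreTable) -> pd.DataFrame:
    """(sender, receiver) x ligand matrix of deltas.

    Multiple receptors per ligand are aggregated by the delta of maximal
    absolute value; rows and columns are ordered by average-linkage
    hierarchical clustering on Euclidean distance (deterministic).
    """
    frame = table.frame.dropna(subset=["delta"])
    if frame.empty:
        raise ValueError("score table is empty")

    def _abs_max(g: pd.Series) -> float:
        return float(g.loc[g.abs().idxmax()])

    agg = (
        frame.groupby(["sender", "receiver", "ligand"], sort=True)["delta"]
        .apply(_abs_max)
        .reset_index()
    )
    agg["pair"] = agg["sender"] + "->" + agg["receiver"]
    mat = agg.pivot_table(index="pair", columns="ligand", values="delta", fill_value=0.0)
    mat = mat.sort_index(axis=0).sort_index(axis=1)

    def _order(values: np.ndarray) -> np.ndarray:
        if values.shape[0] < 3:
            return np.arange(values.shape[0])
        return leaves_list(linkage(values, method="average", metric="euclidean"))

    mat = mat.iloc[_order(mat.to_numpy()), :]
    mat = mat.iloc[:, _order(mat.to_numpy().T)]
    return mat


def lr_network_communities(pairs: LRPairTable, seed: int = 0) -> LRNetwork:
    """Gene graph with LR-pair edges; communities by label propagation."""
    if not pairs.pairs:
        raise ValueError("need at least one LR pair")
    g = nx.Graph()
    for lig, rec in pairs.pairs:
        g.add_edge(lig, rec)
    communities = label_propagation_communities(g, seed=seed)
    return LRNetwork(graph=g, communities=communities)
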