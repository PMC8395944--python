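"""kNN-graph construction and label-propagation community detection.

Label propagation is asynchronous: nodes are visited in a seeded random
order, each adopting the most frequent label among its neighbors (random
tie-break from the same stream), until a full pass changes nothing or
``max_iter`` passes elapse.  The same routine clusters cells and, in the
ligand-receptor module, genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .qc_preprocess import ExprMatrix

__all__ = ["NeighborGraph", "build_knn_graph", "label_propagation_communities"]


@dataclass
class NeighborGraph:
    """Undirected weighted neighbor graph over cell ids."""

    graph: nx.Graph
    k: int

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


def pca_embed(values: np.ndarray, n_pcs: int) -> np.ndarray:
    """Exact-SVD PCA on the centered matrix (desk-scale inputs)."""
    centered = values - values.mean(axis=0)
    n_pcs = min(n_pcs, min(centered.shape))
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def build_knn_graph(expr: ExprMatrix, k: int = 15, n_pcs: int = 20) -> NeighborGraph:
    """Undirected kNN graph in PCA space; each directed nearest-neighbor
    relation contributes an (unweighted, weight-1) edge."""
    from sklearn.neighbors import NearestNeighbors

    if k < 1:
        raise ValueError("k must be >= 1")
    if n_pcs < 2:
        raise ValueError("n_pcs must be >= 2")
    if expr.n_cells <= k:
        raise ValueError(f"k={k} must be smaller than the number of cells ({expr.n_cells})")

    pcs = pca_embed(expr.values, n_pcs)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)

    g = nx.Graph()
    g.add_nodes_from(expr.cell_ids)
    ids = expr.cell_ids
    for i, row in enumerate(idx):
        for j in row[1:]:  # skip self
            g.add_edge(ids[i], ids[int(j)], weight=1.0)
    return NeighborGraph(graph=g, k=k)


def label_propagation_communities(
    g: NeighborGraph | nx.Graph, seed: int = 0, max_iter: int = 100
) -> dict:
    """Asynchronous label propagation; returns node -> dense community id.

    Community ids are 0..K-1 ordered by decreasing community size, ties broken
    by the smallest member node id (string order).  Disconnected components
    can never share a label.  Deterministic for a given seed.
    """
    graph = g.graph if isinstance(g, NeighborGraph) else g
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)
    if not nodes:
        return {}
    labels = {node: i for i, node in enumerate(nodes)}

    order = np.arange(len(nodes))
    for _ in range(max_iter):
        rng.shuffle(order)
        changed = False
        for i in order:
            node = nodes[i]
            neigh = list(graph.neighbors(node))
            if not neigh:
                continue
            counts: dict[int, float] = {}
            for nb in neigh:
                w = graph[node][nb].get("weight", 1.0)
                counts[labels[nb]] = counts.get(labels[nb], 0.0) + w
            best = max(counts.values())
            top = [lab for lab, c in counts.items() if c == best]
            new = top[0] if len(top) == 1 else top[int(rng.integers(len(top)))]
            if new != labels[node]:
                labels[node] = new
                changed = True
        if not changed:
            break

    # densify: by decreasing size, ties by smallest member id
    members: dict[int, list] = {}
    for node, lab in labels.items():
        members.setdefault(lab, []).append(node)
    ordered = sorted(
        members.items(), key=lambda kv: (-len(kv[1]), min(str(n) for n in kv[1]))
    )
    remap = {old: new for new, (old, _) in enumerate(ordered)}
    return {node: remap[lab] for node, lab in labels.items()}
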