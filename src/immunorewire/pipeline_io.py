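"""Format round-tripping and pipeline orchestration.

Counts travel as a 10x-style bundle: ``matrix.mtx`` (Matrix Market triplet,
genes x cells) + ``features.tsv`` + ``barcodes.tsv`` + ``cell_metadata.tsv``
(condition and, for synthetic data, the planted type).  ``run_pipeline``
chains the stages with per-stage seeds derived from the global seed, and
records a manifest of output checksums for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .annotate import (
    MarkerPanel,
    annotate_clusters,
    cell_labels_from_clusters,
    default_marker_panel,
)
from .clustering import build_knn_graph, label_propagation_communities
from .diffexpr import de_table, de_test
from .growth import GrowthCurveSet, compare_growth_curves, endpoint_reduction
from .lr_comm import (
    LRPairTable,
    default_lr_pairs,
    lr_delta_heatmap,
    lr_network_communities,
    lr_score,
    select_ligands,
)
from .popfreq import ecdf_compare, ecdf_table
from .qc_preprocess import QCParams, normalize_log1p, qc_filter
from .synthetic_data import CountMatrix

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_counts_bundle",
    "write_counts_bundle",
    "stage_seed",
    "run_pipeline",
]

log = logging.getLogger("immunorewire")


class BundleFormatError(ValueError):
    """Raised when the on-disk counts bundle is inconsistent."""


def write_counts_bundle(m: CountMatrix, out_dir) -> None:
    """Write matrix.mtx (genes x cells) + features/barcodes + cell metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(m.counts.T))
    pd.Series(m.gene_ids).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    m.cell_metadata().to_csv(out / "cell_metadata.tsv", sep="\t", index=False)


def read_counts_bundle(in_dir) -> CountMatrix:
    """Read a bundle written by :func:`write_counts_bundle` (round-trip identity)."""
    src = Path(in_dir)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (src / name).exists():
            raise BundleFormatError(f"missing {name} in {src}")
    try:
        mat = spio.mmread(src / "matrix.mtx")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise BundleFormatError(f"cannot parse {src / 'matrix.mtx'}: {exc}") from exc
    counts = np.asarray(sparse.coo_matrix(mat).todense()).T
    gene_ids = pd.read_csv(src / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cell_ids = pd.read_csv(src / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    if counts.shape != (len(cell_ids), len(gene_ids)):
        raise BundleFormatError(
            f"matrix.mtx is {mat.shape} (genes x cells) but features.tsv has "
            f"{len(gene_ids)} rows and barcodes.tsv has {len(cell_ids)} rows"
        )
    meta_path = src / "cell_metadata.tsv"
    true_type = None
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t").set_index("cell_id")
        if list(meta.index) != cell_ids:
            raise BundleFormatError("cell_metadata.tsv rows do not match barcodes.tsv")
        condition = meta["condition"].astype(str).tolist()
        if "true_type" in meta.columns:
            true_type = meta["true_type"].astype(str).tolist()
    else:
        condition = ["control"] * len(cell_ids)
    if np.issubdtype(counts.dtype, np.floating):
        counts = counts.astype(np.int64)
    return CountMatrix(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        condition=condition,
        true_type=true_type,
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed so toggling one stage never shifts another's RNG."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunConfig:
    """End-to-end run configuration; ``None`` paths fall back to defaults."""

    counts_dir: str
    out_dir: str
    panel_path: str | None = None
    lr_pairs_path: str | None = None
    growth_path: str | None = None
    qc: QCParams = field(default_factory=QCParams)
    scale: float = 1e4
    k: int = 15
    n_pcs: int = 20
    alpha: float = 0.05
    min_pct: float = 0.25
    min_logfc: float = 0.25
    r_min: float = 0.3
    n_perm: int = 10_000
    seed: int = 0
    stages: tuple[str, ...] = ("qc", "cluster", "annotate", "popfreq", "de", "lrscore", "growth")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "qc" in data and isinstance(data["qc"], dict):
            data["qc"] = QCParams(**data["qc"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


@dataclass
class RunManifest:
    seed: int
    version: str
    stages: dict[str, str]  # stage -> "ok" | "skipped" | "failed: ..."
    checksums: dict[str, str]
    started: float
    finished: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
                "checksums": self.checksums,
                "started": self.started,
                "finished": self.finished,
            },
            indent=2,
            sort_keys=True,
        )


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute enabled stages in order; write stage TSVs and a manifest.

    Stage order: qc -> cluster -> annotate -> popfreq/de -> lrscore; growth is
    independent.  A stage failure aborts the run (partial outputs retained and
    flagged in the manifest).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=cfg.seed,
        version=__version__,
        stages={},
        checksums={},
        started=time.time(),
    )
    panel = (
        MarkerPanel.read_tsv(cfg.panel_path) if cfg.panel_path else default_marker_panel()
    )
    pairs = (
        LRPairTable.read_tsv(cfg.lr_pairs_path) if cfg.lr_pairs_path else default_lr_pairs()
    )

    def record(name: str, path: Path) -> None:
        manifest.checksums[str(path.relative_to(out))] = _sha256(path)

    expr = None
    labels: dict[str, str] = {}
    de_results = []

    def _run_stage(name, fn):
        if name not in cfg.stages:
            manifest.stages[name] = "skipped"
            log.info("stage %s skipped", name)
            return
        try:
            fn()
            manifest.stages[name] = "ok"
            log.info("stage %s ok", name)
        except Exception as exc:
            manifest.stages[name] = f"failed: {exc}"
            (out / "manifest.json").write_text(manifest.to_json())
            raise

    counts = read_counts_bundle(cfg.counts_dir)
    clusters: dict[str, int] = {}

    def do_qc():
        nonlocal counts, expr
        counts = qc_filter(counts, cfg.qc)
        expr = normalize_log1p(counts, cfg.scale)
        path = out / "qc_cells.tsv"
        counts.cell_metadata().to_csv(path, sep="\t", index=False)
        record("qc", path)

    def do_cluster():
        nonlocal clusters, expr
        if expr is None:
            expr = normalize_log1p(counts, cfg.scale)
        graph = build_knn_graph(expr, k=cfg.k, n_pcs=cfg.n_pcs)
        clusters = label_propagation_communities(graph, seed=stage_seed(cfg.seed, "cluster"))
        path = out / "clusters.tsv"
        pd.DataFrame(
            sorted(clusters.items()), columns=["cell_id", "cluster"]
        ).to_csv(path, sep="\t", index=False)
        record("cluster", path)

    def do_annotate():
        nonlocal labels
        ann = annotate_clusters(expr, clusters, panel)
        labels = cell_labels_from_clusters(clusters, ann)
        path = out / "annotation.tsv"
        ann.to_frame().to_csv(path, sep="\t", index=False)
        record("annotate", path)
        path2 = out / "cell_labels.tsv"
        pd.DataFrame(sorted(labels.items()), columns=["cell_id", "label"]).to_csv(
            path2, sep="\t", index=False
        )
        record("annotate", path2)

    def do_popfreq():
        comparisons = []
        lab = np.array([labels.get(c) for c in expr.cell_ids], dtype=object)
        cond = np.asarray(expr.condition)
        for ctype in sorted({t for t in labels.values() if t != "unassigned"}):
            n_ctrl = int(((lab == ctype) & (cond == "control")).sum())
            n_trt = int(((lab == ctype) & (cond == "treated")).sum())
            if min(n_ctrl, n_trt) < 5:
                continue
            markers = [g for g, s in panel.signs.get(ctype, {}).items() if s == 1]
            markers = [g for g in markers if g in expr.gene_ids]
            if not markers:
                continue
            comparisons.append(ecdf_compare(expr, labels, ctype, markers))
        path = out / "popfreq.tsv"
        ecdf_table(comparisons).to_csv(path, sep="\t", index=False)
        record("popfreq", path)

    def do_de():
        nonlocal de_results
        de_results = []
        lab = np.array([labels.get(c) for c in expr.cell_ids], dtype=object)
        cond = np.asarray(expr.condition)
        for ctype in sorted({t for t in labels.values() if t != "unassigned"}):
            n_ctrl = int(((lab == ctype) & (cond == "control")).sum())
            n_trt = int(((lab == ctype) & (cond == "treated")).sum())
            if min(n_ctrl, n_trt) < 3:
                continue
            de_results.extend(
                de_test(expr, labels, ctype, min_pct=cfg.min_pct, min_logfc=cfg.min_logfc)
            )
        path = out / "de.tsv"
        de_table(de_results).to_csv(path, sep="\t", index=False)
        record("de", path)

    def do_lrscore():
        selected = select_ligands(de_results, pairs, alpha=cfg.alpha)
        table = lr_score(expr, labels, selected)
        path = out / "lr_scores.tsv"
        table.frame.to_csv(path, sep="\t", index=False)
        record("lrscore", path)
        if not table.frame.dropna(subset=["delta"]).empty:
            heat = lr_delta_heatmap(table)
            hpath = out / "lr_delta_heatmap.csv"
            heat.to_csv(hpath)
            record("lrscore", hpath)
        if selected.pairs:
            net = lr_network_communities(selected, seed=stage_seed(cfg.seed, "lrnet"))
            npath = out / "lr_communities.tsv"
            pd.DataFrame(
                sorted(net.communities.items()), columns=["gene", "community"]
            ).to_csv(npath, sep="\t", index=False)
            record("lrscore", npath)

    def do_growth():
        if cfg.growth_path is None:
            manifest.stages["growth"] = "skipped"
            return
        curves = GrowthCurveSet.read_tsv(cfg.growth_path)
        result = compare_growth_curves(
            curves, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "growth")
        )
        reduction = endpoint_reduction(curves)
        path = out / "growth.tsv"
        pd.DataFrame(
            [
                {
                    "observed": result.observed,
                    "n_perm": result.n_perm,
                    "p": result.p,
                    "endpoint_reduction": reduction,
                }
            ]
        ).to_csv(path, sep="\t", index=False)
        record("growth", path)

    _run_stage("qc", do_qc)
    if expr is None:
        expr = normalize_log1p(counts, cfg.scale)
    _run_stage("cluster", do_cluster)
    _run_stage("annotate", do_annotate)
    _run_stage("popfreq", do_popfreq)
    _run_stage("de", do_de)
    _run_stage("lrscore", do_lrscore)
    if cfg.growth_path is not None and "growth" in cfg.stages:
        _run_stage("growth", do_growth)
    else:
        manifest.stages["growth"] = "skipped"

    manifest.finished = time.time()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
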