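import numpy as np
import pytest

from immunorewire.annotate import (
    MarkerPanel,
    annotate_clusters,
    cell_labels_from_clusters,
    default_marker_panel,
    marker_positive_fraction,
)
from immunorewire.qc_preprocess import normalize_log1p
from immunorewire.synthetic_data import ScenarioConfig, simulate_counts

from conftest import make_expr


def planted_profile_expr(panel, cells_per_type=20, high=5.0, low=0.1, seed=0):
    """One cluster per panel type with its +1 markers at `high`, rest `low`."""
    rng = np.random.default_rng(seed)
    genes = panel.genes
    rows, clusters, idx = [], {}, 0
    for c, ctype in enumerate(panel.cell_types):
        for _ in range(cells_per_type):
            base = np.array(
                [high if panel.sign(ctype, g) == 1 else low for g in genes]
            )
            rows.append(base + rng.normal(0, 0.01, size=len(genes)).clip(-0.05, 0.05) + 0.05)
            clusters[f"cell{idx}"] = c
            idx += 1
    expr = make_expr(np.array(rows), ["control"] * len(rows), gene_ids=genes)
    return expr, clusters


class TestAnnotateClusters:
    def test_planted_profiles_recover_their_own_labels(self):
        panel = MarkerPanel(
            {
                "M1_committed": {
                    "Csf2rb": 1, "Cd80": 1, "H2-Aa": 1, "H2-Ab1": 1,
                    "Itgax": 1, "Cd86": 1, "Il1b": 1,
                },
                "NK": {"Ncr1": 1, "Cd3e": -1},
                "CD8_T": {"Cd3e": 1, "Cd8a": 1},
            }
        )
        expr, clusters = planted_profile_expr(panel)
        result = annotate_clusters(expr, clusters, panel)
        for c, ctype in enumerate(panel.cell_types):
            assert result.labels[c] == ctype
            assert result.margins[c] > 0

    def test_single_type_panel_labels_everything_margin_zero(self):
        panel = MarkerPanel({"OnlyType": {"g0": 1}})
        expr = make_expr(np.abs(np.random.default_rng(0).normal(1, 0.2, (12, 3))),
                         ["control"] * 12)
        clusters = {cid: i % 2 for i, cid in enumerate(expr.cell_ids)}
        result = annotate_clusters(expr, clusters, panel)
        assert all(lbl == "OnlyType" for lbl in result.labels.values())
        assert all(m == 0 for m in result.margins.values())

    def test_affine_gene_rescaling_invariance(self):
        panel = default_marker_panel()
        expr, clusters = planted_profile_expr(panel, cells_per_type=10)
        base = annotate_clusters(expr, clusters, panel)
        scaled = make_expr(
            expr.values * 3.0 + 1.5, ["control"] * expr.n_cells, gene_ids=expr.gene_ids
        )
        res = annotate_clusters(scaled, clusters, panel)
        assert res.labels == base.labels
        np.testing.assert_allclose(res.scores.values, base.scores.values, atol=1e-9)

    def test_cluster_id_permutation_permutes_results(self):
        panel = MarkerPanel({"A": {"g0": 1}, "B": {"g1": 1}})
        values = np.array([[5.0, 0.1]] * 5 + [[0.1, 5.0]] * 5)
        expr = make_expr(values, ["control"] * 10)
        c1 = {cid: (0 if i < 5 else 1) for i, cid in enumerate(expr.cell_ids)}
        c2 = {cid: (1 if i < 5 else 0) for i, cid in enumerate(expr.cell_ids)}
        r1 = annotate_clusters(expr, c1, panel)
        r2 = annotate_clusters(expr, c2, panel)
        assert r1.labels[0] == r2.labels[1] == "A"
        assert r1.labels[1] == r2.labels[0] == "B"

    def test_small_cluster_unassigned_with_warning(self):
        panel = MarkerPanel({"A": {"g0": 1}, "B": {"g1": 1}})
        values = np.array([[5.0, 0.1]] * 6 + [[0.1, 5.0]] * 2)
        expr = make_expr(values, ["control"] * 8)
        clusters = {cid: (0 if i < 6 else 1) for i, cid in enumerate(expr.cell_ids)}
        with pytest.warns(UserWarning, match="unassigned"):
            result = annotate_clusters(expr, clusters, panel)
        assert result.labels[1] == "unassigned"

    def test_unmatched_panel_genes_warn_not_fail(self):
        panel = MarkerPanel({"A": {"g0": 1, "Missing": 1}, "B": {"g1": 1}})
        values = np.array([[5.0, 0.1]] * 5 + [[0.1, 5.0]] * 5)
        expr = make_expr(values, ["control"] * 10)
        clusters = {cid: (0 if i < 5 else 1) for i, cid in enumerate(expr.cell_ids)}
        with pytest.warns(UserWarning, match="Missing"):
            result = annotate_clusters(expr, clusters, panel)
        assert result.labels[0] == "A"

    def test_fully_unresolvable_type_errors(self):
        panel = MarkerPanel({"A": {"NotThere": 1}})
        expr = make_expr(np.ones((6, 2)), ["control"] * 6)
        clusters = {cid: 0 for cid in expr.cell_ids}
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no resolvable"):
                annotate_clusters(expr, clusters, panel)

    def test_cell_labels_inherit_cluster_labels(self):
        panel = MarkerPanel({"A": {"g0": 1}, "B": {"g1": 1}})
        values = np.array([[5.0, 0.1]] * 5 + [[0.1, 5.0]] * 5)
        expr = make_expr(values, ["control"] * 10)
        clusters = {cid: (0 if i < 5 else 1) for i, cid in enumerate(expr.cell_ids)}
        result = annotate_clusters(expr, clusters, panel)
        labels = cell_labels_from_clusters(clusters, result)
        for cell, cl in clusters.items():
            assert labels[cell] == result.labels[cl]

    def test_panel_tsv_round_trip(self, tmp_path):
        panel = default_marker_panel()
        path = tmp_path / "panel.tsv"
        panel.write_tsv(path)
        loaded = MarkerPanel.read_tsv(path)
        assert {t: {g: s for g, s in tbl.items() if s != 0} for t, tbl in panel.signs.items()} == loaded.signs


class TestMarkerPositiveFraction:
    def test_threshold_zero_all_positive(self):
        expr, labels = make_expr(
            np.full((6, 2), 2.0), ["control"] * 3 + ["treated"] * 3, labels=["T"] * 6
        )
        out = marker_positive_fraction(expr, labels, ["g0"], threshold=0.0)
        assert (out["fraction"] == 1.0).all()

    def test_all_zero_gene_fraction_zero(self):
        values = np.zeros((6, 2))
        values[:, 1] = 1.0
        expr, labels = make_expr(values, ["control"] * 3 + ["treated"] * 3, labels=["T"] * 6)
        out = marker_positive_fraction(expr, labels, ["g0"], threshold=0.5)
        assert (out["fraction"] == 0.0).all()

    def test_type_absent_in_one_condition_flagged_not_zero(self):
        expr, labels = make_expr(
            np.ones((4, 1)), ["control"] * 4, labels=["T"] * 4
        )
        out = marker_positive_fraction(expr, labels, ["g0"], threshold=0.0)
        treated = out[(out["cell_type"] == "T") & (out["condition"] == "treated")]
        assert not treated["defined"].item()
        assert np.isnan(treated["fraction"].item())

    def test_planted_fold_raises_treated_fraction(self):
        panel = MarkerPanel({"M1": {"Ccr5": 1, "Cd80": 1}})
        cfg = ScenarioConfig(
            n_cells_per_condition=400,
            cell_type_proportions={"control": {"M1": 1.0}, "treated": {"M1": 1.0}},
            treatment_effects=[("M1", "Ccr5", 2.0)],
            seed=6,
        )
        m = simulate_counts(cfg, panel=panel)
        expr = normalize_log1p(m)
        labels = dict(zip(m.cell_ids, m.true_type))
        pooled_median = float(np.median(expr.values[:, expr.gene_ids.index("Ccr5")]))
        out = marker_positive_fraction(expr, labels, ["Ccr5"], threshold=pooled_median)
        frac = out.set_index("condition")["fraction"]
        assert frac["treated"] > frac["control"]

    def test_empty_gene_set_rejected(self):
        expr, labels = make_expr(np.ones((4, 1)), ["control"] * 4, labels=["T"] * 4)
        with pytest.raises(ValueError):
            marker_positive_fraction(expr, labels, [], threshold=0.0)
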