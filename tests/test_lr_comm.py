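import numpy as np
import pytest

from immunorewire.diffexpr import DEResult
from immunorewire.lr_comm import (
    LRPairTable,
    default_lr_pairs,
    lr_delta_heatmap,
    lr_network_communities,
    lr_score,
    select_ligands,
)

from conftest import make_expr


def de_result(gene, cell_type="T", p=0.01):
    return DEResult(
        gene=gene, cell_type=cell_type, logfc=1.0, pct_1=0.5, pct_2=0.5, p=p, p_adj=p
    )


def toy_expr(swap_conditions=False):
    """Sender cells (type S) carry ligand L; receiver cells (type R) carry
    receptor Q.  Control means: L=2 in S, Q=3 in R -> score 6."""
    values = np.array(
        [
            # L,   Q
            [1.0, 0.0],
            [2.0, 0.0],
            [3.0, 0.0],  # S control: mean L = 2
            [0.0, 2.0],
            [0.0, 4.0],  # R control: mean Q = 3
            [2.0, 0.0],
            [4.0, 0.0],  # S treated: mean L = 3
            [0.0, 1.0],
            [0.0, 1.0],  # R treated: mean Q = 1
        ]
    )
    cond = ["control"] * 5 + ["treated"] * 4
    if swap_conditions:
        cond = ["treated"] * 5 + ["control"] * 4
    labels = ["S", "S", "S", "R", "R", "S", "S", "R", "R"]
    return make_expr(values, cond, labels=labels, gene_ids=["L", "Q"])


class TestSelectLigands:
    def test_alpha_one_retains_all_tested(self):
        pairs = LRPairTable([("A", "r1"), ("B", "r2")])
        de = [de_result("A", p=0.9), de_result("B", p=0.5)]
        kept = select_ligands(de, pairs, alpha=1.0)
        assert kept.pairs == pairs.pairs

    def test_planted_de_ligand_retained_with_sender_types(self):
        pairs = LRPairTable([("Ccl5", "Ccr5"), ("Ccl5", "Ccr1"), ("Ifng", "Ifngr1")])
        de = [de_result("Ccl5", cell_type="CD8_T", p=0.001), de_result("Ifng", p=0.4)]
        kept = select_ligands(de, pairs, alpha=0.05)
        assert kept.pairs == [("Ccl5", "Ccr5"), ("Ccl5", "Ccr1")]
        assert kept.sender_types["Ccl5"] == ["CD8_T"]

    def test_empty_selection_warns(self):
        pairs = LRPairTable([("A", "r1")])
        with pytest.warns(UserWarning, match="empty"):
            kept = select_ligands([de_result("A", p=0.9)], pairs, alpha=0.05)
        assert kept.pairs == []


class TestLRScore:
    def test_product_of_means(self):
        expr, labels = toy_expr()
        table = lr_score(expr, labels, LRPairTable([("L", "Q")]))
        row = table.frame.set_index(["sender", "receiver"]).loc[("S", "R")]
        assert row["score_control"] == pytest.approx(6.0)  # 2 * 3
        assert row["score_treated"] == pytest.approx(3.0)  # 3 * 1
        assert row["delta"] == pytest.approx(-3.0)

    def test_all_ordered_type_pairs_present_including_autocrine(self):
        expr, labels = toy_expr()
        table = lr_score(expr, labels, LRPairTable([("L", "Q")]))
        assert set(map(tuple, table.frame[["sender", "receiver"]].values)) == {
            ("S", "S"), ("S", "R"), ("R", "S"), ("R", "R"),
        }

    def test_condition_swap_negates_delta(self):
        expr_a, labels = toy_expr()
        expr_b, _ = toy_expr(swap_conditions=True)
        pairs = LRPairTable([("L", "Q"), ("Q", "L")])
        ta = lr_score(expr_a, labels, pairs).frame
        tb = lr_score(expr_b, labels, pairs).frame
        np.testing.assert_allclose(ta["delta"], -tb["delta"], atol=1e-12)

    def test_absent_gene_pair_skipped(self):
        expr, labels = toy_expr()
        with pytest.warns(UserWarning, match="skipped"):
            table = lr_score(expr, labels, LRPairTable([("L", "Q"), ("L", "Nope")]))
        assert table.skipped_pairs == [("L", "Nope")]
        assert set(table.frame["receptor"]) == {"Q"}

    def test_bilinear_in_sender_ligand_scaling(self):
        expr, labels = toy_expr()
        scaled = expr.values.copy()
        sender = [i for i, c in enumerate(expr.cell_ids) if labels[c] == "S"]
        scaled[sender, 0] *= 5.0
        expr2, _ = make_expr(
            scaled, expr.condition, labels=[labels[c] for c in expr.cell_ids],
            gene_ids=expr.gene_ids,
        )
        t1 = lr_score(expr, labels, LRPairTable([("L", "Q")])).frame
        t2 = lr_score(expr2, labels, LRPairTable([("L", "Q")])).frame
        sel = t1["sender"] == "S"
        np.testing.assert_allclose(
            t2.loc[sel, "score_control"], 5.0 * t1.loc[sel, "score_control"]
        )

    def test_row_count_reconciles_with_skips(self):
        expr, labels = toy_expr()
        with pytest.warns(UserWarning):
            table = lr_score(
                expr, labels, LRPairTable([("L", "Q"), ("Q", "L"), ("X", "Y")])
            )
        n_types = 2
        assert len(table.frame) == n_types**2 * 2
        assert len(table.skipped_pairs) == 1


class TestDeltaHeatmap:
    def test_single_row(self):
        expr, labels = toy_expr()
        table = lr_score(expr, labels, LRPairTable([("L", "Q")]))
        table.frame = table.frame[
            (table.frame["sender"] == "S") & (table.frame["receiver"] == "R")
        ]
        mat = lr_delta_heatmap(table)
        assert mat.shape == (1, 1)
        assert mat.iloc[0, 0] == pytest.approx(-3.0)

    def test_planted_argmax(self):
        expr, labels = toy_expr()
        mat = lr_delta_heatmap(lr_score(expr, labels, LRPairTable([("L", "Q")])))
        # hand-computed: S->R delta = 3*1 - 2*3 = -3 is the strongest magnitude
        strongest = mat.abs().stack().idxmax()
        assert strongest == ("S->R", "L")

    def test_receptor_aggregation_by_max_abs_delta(self):
        expr, labels = toy_expr()
        # two receptors for the same ligand: Q and a constant-expression clone
        values = np.column_stack([expr.values, expr.values[:, 1] * 0.1])
        expr2, _ = make_expr(
            values, expr.condition, labels=[labels[c] for c in expr.cell_ids],
            gene_ids=["L", "Q", "Q2"],
        )
        table = lr_score(expr2, labels, LRPairTable([("L", "Q"), ("L", "Q2")]))
        mat = lr_delta_heatmap(table)
        assert mat.loc["S->R", "L"] == pytest.approx(-3.0)  # |−3| > |−0.3|


class TestLRNetworkCommunities:
    def test_single_pair_single_community(self):
        net = lr_network_communities(LRPairTable([("A", "B")]), seed=0)
        assert net.n_communities == 1
        assert net.communities["A"] == net.communities["B"]

    def test_disjoint_pair_sets(self):
        net = lr_network_communities(
            LRPairTable([("A", "B"), ("A", "C"), ("X", "Y")]), seed=0
        )
        assert net.n_communities == 2
        assert net.communities["A"] == net.communities["B"] == net.communities["C"]
        assert net.communities["X"] == net.communities["Y"]

    def test_three_disconnected_blocks(self):
        pairs = []
        for block in ("p", "q", "r"):
            ligs = [f"{block}L{i}" for i in range(3)]
            recs = [f"{block}R{i}" for i in range(3)]
            pairs += [(l, r) for l in ligs for r in recs]
        net = lr_network_communities(LRPairTable(pairs), seed=3)
        assert net.n_communities == 3  # disconnected-component oracle

    def test_structure_independent_of_expression(self):
        # communities depend only on the pair table
        a = lr_network_communities(default_lr_pairs(), seed=7)
        b = lr_network_communities(default_lr_pairs(), seed=7)
        assert a.communities == b.communities

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            lr_network_communities(LRPairTable([]))


class TestLRPairTable:
    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            LRPairTable([("A", "B"), ("A", "B")])

    def test_empty_gene_name_rejected(self):
        with pytest.raises(ValueError):
            LRPairTable([("", "B")])

    def test_tsv_round_trip(self, tmp_path):
        pairs = default_lr_pairs()
        path = tmp_path / "pairs.tsv"
        pairs.write_tsv(path)
        assert LRPairTable.read_tsv(path).pairs == pairs.pairs
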