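import numpy as np
import pytest

from warburgph.core_io import CASE, CONTROL, ValidationError
from warburgph.diffexpr import categorize_for_heatmap, differential_expression
from warburgph.transporters import load_default_panel
from tests.conftest import make_matrix
from tests._oracles import rank_sum_p_enumeration


class TestDifferentialExpression:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(0)
        half = rng.normal(6, 1, (5, 10))
        mat = make_matrix(np.hstack([half, half]), 10, 10)
        res = differential_expression(mat)
        assert np.allclose(res.table["log2FC"], 0.0)
        assert (res.table["deg_call"] == "unchanged").all()

    def test_planted_shift_detected(self):
        """A +2 log2 shift at n=20/20 gives FC near 4 and an up call."""
        rng = np.random.default_rng(1)
        ctrl = rng.normal(6, 0.5, (3, 20))
        case = ctrl + 2.0
        mat = make_matrix(np.hstack([case, ctrl]), 20, 20)
        res = differential_expression(mat)
        assert np.allclose(res.table["FC"], 4.0, atol=1e-9)
        assert (res.table["deg_call"] == "up").all()
        assert (res.table["p_value"] < 1e-6).all()

    def test_five_vs_five_matches_exact_enumeration(self):
        """{1..5} vs {6..10}: two-sided rank-sum p = 2/252."""
        mat = make_matrix(np.array([[1., 2, 3, 4, 5, 6, 7, 8, 9, 10]]), 5, 5)
        res = differential_expression(mat)
        p = res.table["p_value"].iloc[0]
        assert p == pytest.approx(2.0 / 252.0, rel=1e-12)
        assert p == pytest.approx(
            rank_sum_p_enumeration([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]), rel=1e-12
        )

    @pytest.mark.parametrize("n1,n2,seed", [(3, 4, 0), (5, 5, 1), (6, 6, 2), (4, 6, 3)])
    def test_exact_p_equals_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        mat = make_matrix(vals.reshape(1, -1), n1, n2)
        p = differential_expression(mat).table["p_value"].iloc[0]
        oracle = rank_sum_p_enumeration(list(vals[:n1]), list(vals[n1:]))
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_label_swap_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(6, 1, (6, 16))
        mat = make_matrix(vals, 8, 8)
        flipped = make_matrix(np.hstack([vals[:, 8:], vals[:, :8]]), 8, 8)
        r1 = differential_expression(mat).table
        r2 = differential_expression(flipped).table
        assert np.allclose(r1["log2FC"], -r2["log2FC"].to_numpy())
        assert np.allclose(r1["p_value"], r2["p_value"].to_numpy())

    def test_fc_equals_two_to_log2fc(self):
        rng = np.random.default_rng(6)
        mat = make_matrix(rng.normal(6, 1, (10, 12)), 6, 6)
        t = differential_expression(mat).table
        assert np.allclose(t["FC"], 2.0 ** t["log2FC"])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(7)
        mat = make_matrix(rng.normal(6, 1, (40, 20)), 10, 10)
        t = differential_expression(mat).table
        assert (t["q_value"] >= t["p_value"] - 1e-15).all()

    def test_threshold_excludes_silent_genes(self):
        rng = np.random.default_rng(8)
        expressed = rng.normal(6, 1, (3, 10))
        silent = rng.normal(0, 1, (2, 10))
        mat = make_matrix(np.vstack([expressed, silent]), 5, 5)
        t = differential_expression(mat, threshold=3.0).table
        assert t["expressed"].tolist() == [True] * 3 + [False] * 2
        assert t["deg_call"].tolist()[3:] == ["not_expressed"] * 2
        assert t["p_value"].isna().tolist()[3:] == [True, True]

    def test_paired_needs_equal_groups(self):
        rng = np.random.default_rng(9)
        mat = make_matrix(rng.normal(6, 1, (3, 7)), 3, 4, paired=True)
        with pytest.raises(ValidationError):
            differential_expression(mat)

    def test_paired_signed_rank_detects_consistent_shift(self):
        rng = np.random.default_rng(10)
        ctrl = rng.normal(6, 1, (2, 10))
        case = ctrl + 1.5
        mat = make_matrix(np.hstack([case, ctrl]), 10, 10, paired=True)
        t = differential_expression(mat).table
        assert (t["p_value"] < 0.01).all()


class TestHeatmapCalls:
    @pytest.mark.parametrize(
        "shift,expected",
        [(0.75, "up"), (0.0, "unchanged"), (-0.625, "down"), (0.5, "unchanged")],
    )
    def test_threshold_rule(self, shift, expected):
        vals = np.full((1, 20), 6.0)
        vals[0, :10] += shift
        mat = make_matrix(vals, 10, 10, genes=["SLC4A2"])
        res = differential_expression(mat)
        assert res.table["heatmap_call"].iloc[0] == expected

    def test_missing_panel_gene_recorded(self):
        rng = np.random.default_rng(1)
        mat = make_matrix(rng.normal(6, 1, (1, 10)), 5, 5, genes=["SLC4A2"])
        res = differential_expression(mat)
        calls = categorize_for_heatmap(res, load_default_panel())
        assert calls.loc["SLC4A2", "call"] in {"up", "down", "unchanged"}
        assert calls.loc["SLC16A1", "call"] == "missing"
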