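import numpy as np
import pytest

from warburgph.core_io import ExpressionMatrix, GeneSet, ValidationError
from warburgph.genesetcorr import (
    enrich_genesets,
    gene_vs_set_correlation,
    hypergeometric_tail,
    overlap_test,
    principal_curve,
    set_vs_set_correlation,
)
from warburgph.simulate import LatentLink, SimulationSpec, simulate_dataset
from tests.conftest import make_matrix
from tests._oracles import hypergeom_tail_enumeration


class TestHypergeometricTail:
    @pytest.mark.parametrize(
        "N,M,n,m,expected",
        [
            (10, 3, 3, 3, 1.0 / 120.0),
            (10, 3, 3, 1, 1.0 - 35.0 / 120.0),
            (10, 3, 3, 0, 1.0),
        ],
    )
    def test_exact_values(self, N, M, n, m, expected):
        assert hypergeometric_tail(N, M, n, m) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_on_sampled_small_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            N = int(rng.integers(2, 11))
            M = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            m = int(rng.integers(0, min(n, M) + 1))
            assert hypergeometric_tail(N, M, n, m) == pytest.approx(
                hypergeom_tail_enumeration(N, M, n, m), abs=1e-12
            )

    def test_monotone_nonincreasing_in_m(self):
        for N, M, n in [(12, 5, 6), (9, 4, 4), (20, 8, 10)]:
            tails = [hypergeometric_tail(N, M, n, m) for m in range(min(n, M) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_tail(10, 3, 3, 4)
        with pytest.raises(ValidationError):
            hypergeometric_tail(5, 6, 2, 1)


class TestGeneVsSet:
    def _linked_matrix(self, rho=0.9, n=100, seed=2):
        spec = SimulationSpec(
            n_genes=40, n_case=n // 2, n_control=n - n // 2, seed=seed,
            nonexpressed_fraction=0.0,
            latent_links=[LatentLink(("S1", "S2", "S3", "S4"), ("Q",), rho)],
        )
        mat, _ = simulate_dataset(spec)
        return mat, GeneSet.from_iterable("set", ["S1", "S2", "S3", "S4"])

    def test_exact_linear_combination_gives_r2_one(self):
        rng = np.random.default_rng(3)
        two = rng.normal(6, 1, (2, 30))
        sub = np.vstack([two, two[0] + two[1]])  # rank-2 set: PC1+PC2 explain all
        sets = np.vstack([sub, np.zeros((1, 30))])
        mat = make_matrix(sets, 15, 15, genes=["S1", "S2", "S3", "Q"])
        centered = sub - sub.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
        mat.values.loc["Q"] = 2.0 * (u[:, 0] * s[0]) + 1.0  # exact PC1 function
        rep = gene_vs_set_correlation("Q", GeneSet.from_iterable("set", ["S1", "S2", "S3"]), mat)
        assert rep.method == "pc_regression"
        assert rep.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_collinear_set_takes_pc_branch(self):
        base = np.linspace(0, 1, 20)
        vals = np.vstack([base, 2 * base + 1, -base, np.random.default_rng(0).normal(6, 1, 20)])
        mat = make_matrix(vals, 10, 10, genes=["S1", "S2", "S3", "Q"])
        rep = gene_vs_set_correlation("Q", GeneSet.from_iterable("set", ["S1", "S2", "S3"]), mat)
        assert rep.method == "pc_regression"
        assert rep.variance_explained == pytest.approx(1.0, abs=1e-12)

    def test_linked_gene_is_significant(self):
        mat, gs = self._linked_matrix()
        rep = gene_vs_set_correlation("Q", gs, mat)
        assert rep.method == "pc_regression"
        assert rep.p_value < 1e-6

    def test_independent_gene_null_calibration(self):
        """With no planted link, p > 0.05 in at least 90% of replicates."""
        hits = 0
        reps = 40
        for seed in range(reps):
            spec = SimulationSpec(
                n_genes=20, n_case=100, n_control=100, seed=seed,
                nonexpressed_fraction=0.0,
                latent_links=[LatentLink(("S1", "S2", "S3", "S4"), ("S5",), 0.9)],
                planted_fc={"Q": 1.0},
            )
            mat, _ = simulate_dataset(spec)
            rep = gene_vs_set_correlation(
                "Q", GeneSet.from_iterable("set", ["S1", "S2", "S3", "S4", "S5"]), mat
            )
            if rep.p_value > 0.05:
                hits += 1
        assert hits >= 0.9 * reps

    def test_gene_inside_set_rejected(self):
        mat, gs = self._linked_matrix()
        with pytest.raises(ValidationError):
            gene_vs_set_correlation("S1", gs, mat)

    def test_low_variance_gate_falls_back_to_overlap(self):
        rng = np.random.default_rng(4)
        mat = make_matrix(rng.normal(6, 1, (30, 60)), 30, 30)
        gs = GeneSet.from_iterable("set", [f"g{i}" for i in range(10)])
        rep = gene_vs_set_correlation("g20", gs, mat, variance_gate=0.99)
        assert rep.method == "overlap_test"
        assert rep.N == 29
        assert 0.0 <= rep.P <= 1.0


class TestOverlapTest:
    def test_no_selection_is_degenerate_p_one(self):
        rng = np.random.default_rng(5)
        mat = make_matrix(rng.normal(6, 1, (15, 40)), 20, 20)
        rep = overlap_test("g0", GeneSet.from_iterable("set", ["g1", "g2", "g3"]), mat, alpha=1e-12)
        assert rep.degenerate
        assert rep.P == 1.0
        assert rep.n == 0

    def test_planted_correlations_selected_and_enriched(self):
        spec = SimulationSpec(
            n_genes=60, n_case=100, n_control=100, seed=6, nonexpressed_fraction=0.0,
            latent_links=[LatentLink(("Q",), ("S1", "S2", "S3", "S4", "S5"), 0.85)],
        )
        mat, _ = simulate_dataset(spec)
        rep = overlap_test("Q", GeneSet.from_iterable("set", ["S1", "S2", "S3", "S4", "S5"]), mat)
        assert rep.m == 5
        assert rep.P < 1e-4


class TestEnrichment:
    LIB = [
        GeneSet.from_iterable("inside", ["a", "b", "c"]),
        GeneSet.from_iterable("partial", ["a", "x", "y", "z", "w"]),
        GeneSet.from_iterable("disjoint", ["p", "q"]),
    ]

    def test_contained_query_ranks_first_disjoint_p_one(self):
        table = enrich_genesets(frozenset({"a", "b", "c"}), self.LIB, N=20)
        assert table.index[0] == "inside"
        assert table.loc["disjoint", "P"] == 1.0
        assert (table["P"].diff().dropna() >= -1e-15).all()  # sorted ascending

    def test_exact_tail_value(self):
        # N=20, M=5, n=4, m=2
        lib = [GeneSet.from_iterable("S", ["a", "b", "x1", "x2", "x3"])]
        table = enrich_genesets(frozenset({"a", "b", "u", "v"}), lib, N=20)
        from math import comb
        expected = 1.0 - (comb(5, 0) * comb(15, 4) + comb(5, 1) * comb(15, 3)) / comb(20, 4)
        assert table.loc["S", "P"] == pytest.approx(expected, abs=1e-12)

    def test_empty_library_rejected(self):
        with pytest.raises(ValidationError):
            enrich_genesets(frozenset({"a"}), [], N=10)


class TestPrincipalCurve:
    def _base_matrix(self, seed=7, n=120):
        spec = SimulationSpec(
            n_genes=20, n_case=n // 2, n_control=n - n // 2, seed=seed,
            nonexpressed_fraction=0.0,
            latent_links=[LatentLink(("A1", "A2", "A3"), ("B1", "B2", "B3"), 0.8)],
        )
        mat, _ = simulate_dataset(spec)
        return mat

    def test_identical_submatrices_give_pcc_one(self):
        mat = self._base_matrix()
        df = mat.values.copy()
        for a, c in zip(["A1", "A2", "A3"], ["C1", "C2", "C3"]):
            df.loc[c] = df.loc[a].to_numpy()
        m2 = ExpressionMatrix(values=df, sample_groups=dict(mat.sample_groups))
        rep = set_vs_set_correlation(
            GeneSet.from_iterable("X", ["A1", "A2", "A3"]),
            GeneSet.from_iterable("Y", ["C1", "C2", "C3"]),
            m2,
        )
        assert rep.pcc == pytest.approx(1.0, abs=1e-9)

    def test_antithetic_submatrices_give_pcc_minus_one(self):
        mat = self._base_matrix()
        df = mat.values.copy()
        sub = df.loc[["A1", "A2", "A3"]]
        centered = sub.sub(sub.mean(axis=1), axis=0)
        for i, c in enumerate(["D1", "D2", "D3"]):
            df.loc[c] = -centered.iloc[i].to_numpy()
        m2 = ExpressionMatrix(values=df, sample_groups=dict(mat.sample_groups))
        rep = set_vs_set_correlation(
            GeneSet.from_iterable("X", ["A1", "A2", "A3"]),
            GeneSet.from_iterable("Y", ["D1", "D2", "D3"]),
            m2,
        )
        assert rep.pcc == pytest.approx(-1.0, abs=1e-9)

    def test_linked_sets_correlate(self):
        rep = set_vs_set_correlation(
            GeneSet.from_iterable("X", ["A1", "A2", "A3"]),
            GeneSet.from_iterable("Y", ["B1", "B2", "B3"]),
            self._base_matrix(),
        )
        assert rep.pcc > 0.5
        assert rep.p_value < 1e-6

    def test_shared_genes_removed_before_fitting(self):
        rep = set_vs_set_correlation(
            GeneSet.from_iterable("X", ["A1", "A2", "A3", "Z"]),
            GeneSet.from_iterable("Y", ["B1", "B2", "B3", "Z"]),
            self._base_matrix(),
        )
        assert rep.notes["n_shared_removed"] == 1

    def test_line_data_projection_recovers_coordinate(self):
        """Points exactly on a line: arc-length equals the line coordinate."""
        t = np.sort(np.random.default_rng(8).normal(0, 2, 80))
        X = np.column_stack([t, 2 * t, -t])
        lam = principal_curve(X)
        r = abs(np.corrcoef(lam, t)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(ValidationError):
            principal_curve(np.zeros((20, 3)))
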