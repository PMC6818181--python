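import numpy as np
import pytest

from warburgph.core_io import ValidationError
from warburgph.simulate import (
    LatentLink,
    SimulationSpec,
    cancer_like_spec,
    simulate_dataset,
    simulate_timecourse,
)


class TestSimulateDataset:
    def test_deterministic_under_fixed_seed(self):
        spec = cancer_like_spec(seed=5, n_case=20, n_control=20)
        m1, _ = simulate_dataset(spec)
        m2, _ = simulate_dataset(cancer_like_spec(seed=5, n_case=20, n_control=20))
        assert m1.values.equals(m2.values)

    def test_different_seed_different_data(self):
        m1, _ = simulate_dataset(cancer_like_spec(seed=1, n_case=10, n_control=10))
        m2, _ = simulate_dataset(cancer_like_spec(seed=2, n_case=10, n_control=10))
        assert not m1.values.equals(m2.values)

    def test_planted_fold_change_recovered(self):
        """Empirical linear FC of a planted FC=4 gene lands near 4 at n=50/50."""
        spec = SimulationSpec(
            n_genes=50, n_case=50, n_control=50, seed=1, planted_fc={"LDHA": 4.0}
        )
        mat, truth = simulate_dataset(spec)
        row = mat.values.loc["LDHA"]
        fc = 2.0 ** (row[mat.case_samples].mean() - row[mat.control_samples].mean())
        assert 3.2 <= fc <= 5.0
        assert truth.planted_log2fc["LDHA"] == pytest.approx(2.0)

    def test_unlinked_genes_are_uncorrelated(self):
        """With no latent links the mean off-diagonal |r| stays small."""
        spec = SimulationSpec(n_genes=30, n_case=100, n_control=100, seed=3,
                              nonexpressed_fraction=0.0)
        mat, _ = simulate_dataset(spec)
        r = np.corrcoef(mat.values.to_numpy())
        off = np.abs(r[np.triu_indices_from(r, k=1)])
        assert off.mean() < 0.1

    def test_latent_link_induces_target_correlation(self):
        spec = SimulationSpec(
            n_genes=10, n_case=250, n_control=250, seed=4, nonexpressed_fraction=0.0,
            latent_links=[LatentLink(("A1", "A2"), ("B1", "B2"), 0.8)],
        )
        mat, _ = simulate_dataset(spec)
        r = np.corrcoef(mat.values.loc["A1"], mat.values.loc["B1"])[0, 1]
        assert r == pytest.approx(0.8, abs=0.08)

    def test_negative_rho_anticorrelates_across_sets(self):
        spec = SimulationSpec(
            n_genes=6, n_case=250, n_control=250, seed=4, nonexpressed_fraction=0.0,
            latent_links=[LatentLink(("A1",), ("B1",), -0.7)],
        )
        mat, _ = simulate_dataset(spec)
        r = np.corrcoef(mat.values.loc["A1"], mat.values.loc["B1"])[0, 1]
        assert r == pytest.approx(-0.7, abs=0.1)

    def test_marginal_is_bimodal(self):
        spec = SimulationSpec(n_genes=300, n_case=20, n_control=20, seed=0)
        mat, truth = simulate_dataset(spec)
        pooled = mat.values.to_numpy().ravel()
        lo = pooled[pooled < 3].mean()
        hi = pooled[pooled > 3].mean()
        assert lo == pytest.approx(0.0, abs=0.3)
        assert hi == pytest.approx(6.0, abs=0.3)
        assert len(truth.nonexpressed_genes) == pytest.approx(100, abs=2)

    def test_contradictory_links_rejected(self):
        spec = SimulationSpec(
            n_genes=10, planted_fc={},
            latent_links=[
                LatentLink(("A",), ("B",), 0.5),
                LatentLink(("A",), ("C",), 0.9),
            ],
        )
        with pytest.raises(ValidationError):
            simulate_dataset(spec)

    def test_nonpositive_fc_rejected(self):
        with pytest.raises(ValidationError):
            simulate_dataset(SimulationSpec(planted_fc={"X": 0.0}))


class TestSimulateTimecourse:
    def test_noiseless_trends_are_monotone(self):
        spec = SimulationSpec(
            seed=0, trends={"R": "rising", "F": "falling"}, timecourse_noise_sd=0.0
        )
        tc = simulate_timecourse(spec)
        assert tc.shape == (2, 19)
        assert np.all(np.diff(tc.loc["R"]) > 0)
        assert np.all(np.diff(tc.loc["F"]) < 0)

    def test_reproducible_given_seed(self):
        spec = SimulationSpec(seed=9, trends={"G": "peak_then_decline"})
        assert simulate_timecourse(spec).equals(simulate_timecourse(spec))

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValidationError):
            simulate_timecourse(SimulationSpec(n_timepoints=5, trends={"G": "rising"}))
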