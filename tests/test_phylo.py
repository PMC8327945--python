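"""Phylogenetic covariance, Gibbs sampler, Geweke diagnostic, simplification."""

import numpy as np
import pandas as pd
import pytest

from karyoscale import (
    AmongSpeciesSimSpec,
    fit_phylo_mm,
    geweke_z,
    parse_newick,
    phylo_covariance,
    simulate_among_species,
    summarize_and_simplify,
)
from karyoscale.phylo import PhyloModelSpec


class TestCovariance:
    def test_two_independent_tips(self):
        A = phylo_covariance(parse_newick("(A:1,B:1);")).to_numpy()
        assert A == pytest.approx(np.eye(2))

    def test_three_tip_shared_history(self):
        A = phylo_covariance(parse_newick("((A:1,B:1):1,C:2);"), ["A", "B", "C"])
        assert A.to_numpy() == pytest.approx(
            np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        )

    def test_star_tree_diagonal(self):
        A = phylo_covariance(parse_newick("(A:3,B:3,C:3,D:3);")).to_numpy()
        assert A == pytest.approx(3 * np.eye(4))

    def test_missing_species_listed(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="missing from tree.*C"):
            phylo_covariance(tree, ["A", "C"])

    def test_psd_on_simulated_trees(self):
        for seed in range(5):
            from karyoscale import simulate_yule_tree

            tree = simulate_yule_tree(20, 1.0, seed=seed)
            A = phylo_covariance(tree).to_numpy()
            assert (A == A.T).all()
            assert np.linalg.eigvalsh(A).min() >= -1e-8


class TestGeweke:
    def test_iid_chain_within_band(self):
        excursions = sum(
            abs(geweke_z(np.random.default_rng(s).standard_normal(4900))) > 2
            for s in range(20)
        )
        assert excursions <= 1

    def test_trending_chain_flagged(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 10, 2000) + rng.standard_normal(2000)
        assert abs(geweke_z(x)) > 2

    def test_constant_chain_error(self):
        with pytest.raises(ValueError, match="constant"):
            geweke_z(np.ones(500))

    def test_short_chain_error(self):
        with pytest.raises(ValueError, match="too short"):
            geweke_z(np.arange(50))


class TestSampler:
    def test_retained_sample_arithmetic(self):
        spec = PhyloModelSpec(nitt=5000, thin=10, burnin=1000)
        assert spec.n_retained == 400
        spec2 = PhyloModelSpec()  # study defaults
        assert (spec2.nitt, spec2.thin, spec2.burnin) == (500_000, 100, 10_000)
        assert spec2.n_retained == 4900

    def test_chain_length_matches_settings(self, small_among):
        tree, table, _ = small_among
        spec = PhyloModelSpec(
            nitt=3000, thin=5, burnin=500, n_chains=2, seed=1, interaction=False
        )
        fit = fit_phylo_mm(spec, table, tree)
        assert all(len(ch) == 500 for ch in fit.chains)
        assert fit.summary.n_retained == 500

    def test_streaming_reproducibility(self, small_among):
        """Extending nitt leaves the earlier retained samples unchanged."""
        tree, table, _ = small_among
        base = dict(thin=5, burnin=500, n_chains=1, seed=3, interaction=False)
        short = fit_phylo_mm(PhyloModelSpec(nitt=2000, **base), table, tree)
        long = fit_phylo_mm(PhyloModelSpec(nitt=3500, **base), table, tree)
        n = len(short.chains[0])
        pd.testing.assert_frame_equal(short.chains[0], long.chains[0].iloc[:n])

    def test_recovers_slope_without_phylogenetic_signal(self):
        """Zero phylogenetic variance, tight noise: posterior close to truth."""
        spec = AmongSpeciesSimSpec(
            clades=("fish",), n_species_per_clade=40, true_b=0.7,
            phylo_sd_nucleus=0.0, iid_sd_nucleus=0.03, dna_noise_sd=0.02, seed=5,
        )
        tree, table, _ = simulate_among_species(spec)
        ms = PhyloModelSpec(
            nitt=8000, thin=5, burnin=1000, n_chains=1, seed=2, interaction=False
        )
        fit = fit_phylo_mm(ms, table, tree)
        mean, (lo, hi) = fit.summary.coefficients["log10_cell"]
        post_sd = fit.chains[0]["log10_cell"].std()
        assert abs(mean - 0.7) < 3 * post_sd

    def test_duplicate_species_rejected(self, small_among):
        tree, table, _ = small_among
        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="aggregate"):
            fit_phylo_mm(PhyloModelSpec(nitt=200, burnin=10), dup, tree)


class TestSimplification:
    def _mock_chains(self, interaction_ci_center, n=500, seed=0):
        rng = np.random.default_rng(seed)
        cols = {
            "intercept": rng.normal(0, 0.05, n),
            "log10_cell": rng.normal(0.7, 0.05, n),
            "clade[fish]": rng.normal(0.1, 0.05, n),
            "log10_cell:clade[fish]": rng.normal(interaction_ci_center, 0.05, n),
            "var_phylo": rng.gamma(2, 0.05, n),
            "var_resid": rng.gamma(2, 0.05, n),
        }
        return [pd.DataFrame(cols)]

    def _mock_main_chains(self, n=500, seed=1):
        rng = np.random.default_rng(seed)
        return [
            pd.DataFrame(
                {
                    "intercept": rng.normal(0, 0.05, n),
                    "log10_cell": rng.normal(0.7, 0.05, n),
                    "clade[fish]": rng.normal(0.1, 0.05, n),
                    "var_phylo": rng.gamma(2, 0.05, n),
                    "var_resid": rng.gamma(2, 0.05, n),
                }
            )
        ], ["intercept", "log10_cell", "clade[fish]"]

    def test_interaction_spanning_zero_dropped(self):
        spec = PhyloModelSpec(nitt=1000, burnin=100, thin=1)
        terms = ["intercept", "log10_cell", "clade[fish]", "log10_cell:clade[fish]"]
        summary = summarize_and_simplify(
            self._mock_chains(0.02), spec, terms, refit=self._mock_main_chains
        )
        assert summary.interaction_dropped
        assert "log10_cell:clade[fish]" not in summary.coefficients

    def test_significant_interaction_kept(self):
        spec = PhyloModelSpec(nitt=1000, burnin=100, thin=1)
        terms = ["intercept", "log10_cell", "clade[fish]", "log10_cell:clade[fish]"]
        summary = summarize_and_simplify(
            self._mock_chains(0.3), spec, terms, refit=self._mock_main_chains
        )
        assert not summary.interaction_dropped
        assert "log10_cell:clade[fish]" in summary.coefficients

    def test_power_to_retain_genuine_clade_differences(self):
        """Clades with b = 0.6 vs 0.9 at low noise keep the interaction."""
        kept = 0
        reps = 30
        for i in range(reps):
            spec = AmongSpeciesSimSpec(
                clades=("birds", "fish"), n_species_per_clade=20,
                true_b={"birds": 0.6, "fish": 0.9},
                phylo_sd_nucleus=0.02, iid_sd_nucleus=0.05, dna_noise_sd=0.02,
                seed=500 + i,
            )
            tree, table, _ = simulate_among_species(spec)
            ms = PhyloModelSpec(
                nitt=3000, thin=3, burnin=600, n_chains=1, seed=900 + i
            )
            fit = fit_phylo_mm(ms, table, tree)
            kept += not fit.summary.interaction_dropped
        assert kept / reps >= 0.9
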