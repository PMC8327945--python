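"""Simulators: determinism, invariants, and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from karyoscale import (
    AmongSpeciesSimSpec,
    SelectionSimSpec,
    fit_allometry,
    simulate_among_species,
    simulate_bm_on_tree,
    simulate_selection_experiment,
    simulate_within_species,
    simulate_yule_tree,
    write_newick,
)
from karyoscale.io import validate_cell_table, validate_species_table
from karyoscale.phylo import phylo_covariance


def tree_height(tree):
    return max(tree.calc_node_root_distances(return_leaf_distances_only=True))


class TestYule:
    def test_single_tip(self):
        tree = simulate_yule_tree(1, 1.0, seed=0)
        assert len(tree.leaf_nodes()) == 1
        assert sum(1 for n in tree.preorder_node_iter() if not n.is_leaf()) == 0

    def test_deterministic_under_seed(self):
        t1 = simulate_yule_tree(8, 1.0, seed=11)
        t2 = simulate_yule_tree(8, 1.0, seed=11)
        assert write_newick(t1) == write_newick(t2)

    def test_ultrametric_unique_tips(self):
        tree = simulate_yule_tree(16, 2.0, seed=3)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        assert len(set(labels)) == 16
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        assert np.ptp(depths) < 1e-9

    def test_mean_height_matches_yule_expectation(self):
        """E[height] = Σ_{k=2}^{n} 1/(k·λ) for the pure-birth process."""
        n, lam, reps = 200, 1.0, 500
        expected = sum(1.0 / k for k in range(2, n + 1)) / lam
        # height = Σ_{k=2}^{n-1} Exp(kλ) + Exp(nλ), independent terms
        var = sum(1.0 / k**2 for k in range(2, n)) / lam**2 + 1.0 / (n * lam) ** 2
        heights = [
            tree_height(simulate_yule_tree(n, lam, seed=1000 + i)) for i in range(reps)
        ]
        se = np.sqrt(var / reps)
        assert abs(np.mean(heights) - expected) < 3 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(0, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_yule_tree(5, -1.0, seed=0)


class TestBrownianMotion:
    def test_zero_rate_copies_root(self):
        tree = simulate_yule_tree(10, 1.0, seed=1)
        vals = simulate_bm_on_tree(tree, root_value=2.5, rate=0.0, seed=2)
        assert set(vals.values()) == {2.5}

    def test_deterministic_under_seed(self):
        tree = simulate_yule_tree(10, 1.0, seed=1)
        v1 = simulate_bm_on_tree(tree, 0.0, 1.0, seed=9)
        v2 = simulate_bm_on_tree(tree, 0.0, 1.0, seed=9)
        assert v1 == v2

    def test_contrast_variance_two_tips(self):
        """Var(tip1 − tip2) = 2·rate on a two-tip unit-branch tree."""
        from karyoscale import parse_newick

        rate, reps = 0.7, 2000
        diffs = []
        for i in range(reps):
            tree = parse_newick("(A:1,B:1);")
            vals = simulate_bm_on_tree(tree, 0.0, rate, seed=i)
            diffs.append(vals["A"] - vals["B"])
        target = 2 * rate
        # SE of a sample variance of normal data: var·sqrt(2/(n-1))
        se = target * np.sqrt(2.0 / (reps - 1))
        assert abs(np.var(diffs, ddof=1) - target) < 3 * se

    def test_negative_rate_rejected(self):
        tree = simulate_yule_tree(3, 1.0, seed=1)
        with pytest.raises(ValueError):
            simulate_bm_on_tree(tree, 0.0, -1.0, seed=0)


class TestAmongSpecies:
    def test_noiseless_isometry_constant_ratio(self):
        spec = AmongSpeciesSimSpec(
            clades=("fish",), n_species_per_clade=20, true_b=1.0, true_log10_a=-1.3,
            phylo_sd_nucleus=0.0, iid_sd_nucleus=0.0, dna_noise_sd=0.0, seed=0,
        )
        _, table, _ = simulate_among_species(spec)
        ratio = table["nucleus_volume_um3"] / table["cell_volume_um3"]
        assert np.ptp(ratio) < 1e-9
        assert ratio.iloc[0] == pytest.approx(10**-1.3)

    def test_noiseless_regression_exact(self):
        spec = AmongSpeciesSimSpec(
            clades=("fish",), n_species_per_clade=30, true_b=0.7,
            phylo_sd_nucleus=0.0, iid_sd_nucleus=0.0, dna_noise_sd=0.0, seed=1,
        )
        _, table, _ = simulate_among_species(spec)
        fit = fit_allometry(table["cell_volume_um3"], table["nucleus_volume_um3"])
        assert fit.b == pytest.approx(0.7, abs=1e-10)

    def test_ols_unbiased_for_planted_b(self):
        """Mean OLS estimate over seeds stays within 0.02 of the planted 0.7."""
        ests = []
        for seed in range(60):
            spec = AmongSpeciesSimSpec(
                clades=("fish",), n_species_per_clade=60, true_b=0.7, seed=seed
            )
            _, table, _ = simulate_among_species(spec)
            ests.append(
                fit_allometry(table["cell_volume_um3"], table["nucleus_volume_um3"]).b
            )
        assert abs(np.mean(ests) - 0.7) < 0.02

    def test_output_valid_and_tips_match(self, small_among):
        tree, table, truth = small_among
        validate_species_table(table, clades=None)
        tips = {l.taxon.label for l in tree.leaf_node_iter()}
        assert set(table["species"]) == tips
        assert truth["true_b"] == {"birds": 0.7, "fish": 0.7}
        # covariance of the grafted tree is PSD
        A = phylo_covariance(tree).to_numpy()
        assert np.linalg.eigvalsh(A).min() > -1e-8

    def test_deterministic(self):
        spec = AmongSpeciesSimSpec(clades=("fish",), n_species_per_clade=10, seed=4)
        _, t1, _ = simulate_among_species(spec)
        _, t2, _ = simulate_among_species(spec)
        pd.testing.assert_frame_equal(t1, t2)


class TestWithinSpecies:
    def test_noiseless_constant_ratio(self):
        t = simulate_within_species(b=1.0, log10_a=-1.0, n=50, noise_sd_log10=0.0, seed=0)
        ratio = t["nucleus_volume_um3"] / t["cell_volume_um3"]
        assert np.allclose(ratio, 0.1)

    def test_boundary_passes_min_n_filter(self):
        from karyoscale import filter_cell_table

        t = simulate_within_species(b=0.7, log10_a=-1.0, n=20, seed=1)
        assert len(filter_cell_table(t, min_n=20)) == 20

    def test_invariants_hold(self):
        t = simulate_within_species(b=0.58, log10_a=-0.3, n=500, seed=2)
        validate_cell_table(t)

    def test_retry_bound_raises_with_impossible_parameters(self):
        # nucleus systematically above cell volume cannot be repaired
        with pytest.raises(RuntimeError, match="nucleus < cell"):
            simulate_within_species(b=1.0, log10_a=0.5, n=50, seed=3)

    def test_deterministic(self):
        t1 = simulate_within_species(b=0.6, log10_a=-1.0, n=100, seed=9)
        t2 = simulate_within_species(b=0.6, log10_a=-1.0, n=100, seed=9)
        pd.testing.assert_frame_equal(t1, t2)


class TestSelectionExperiment:
    def test_noiseless_pooled_ols_recovers_slope(self):
        spec = SelectionSimSpec(
            lineage_slope_sd=0.0, lineage_intercept_sd=0.0, lineage_cell_sd=0.0,
            cell_noise_sd=0.0, generation_block_effect=0.0, seed=0,
        )
        cells, truth = simulate_selection_experiment(spec)
        fit = fit_allometry(cells["cell_volume_um3"], cells["nucleus_volume_um3"])
        assert fit.b == pytest.approx(truth["true_slope"], abs=1e-10)

    def test_treatment_mean_ratio_near_printed_means(self, selection_data):
        cells, _ = selection_data
        means = cells.groupby("treatment")["cell_volume_um3"].mean()
        assert means["large"] / means["small"] == pytest.approx(915 / 97, abs=0.5)

    def test_sample_sizes_match_design(self, selection_data):
        cells, _ = selection_data
        by_gen = cells.groupby("generation").size()
        assert by_gen[350] == 1332
        assert by_gen[450] == 1058
        # 12 lineages per treatment per generation
        units = cells.groupby(["generation", "treatment"])["lineage"].nunique()
        assert (units == 12).all()

    def test_byte_identical_under_seed(self):
        spec = SelectionSimSpec(seed=7)
        t1, _ = simulate_selection_experiment(spec)
        t2, _ = simulate_selection_experiment(spec)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invariants(self, selection_data):
        cells, _ = selection_data
        validate_cell_table(cells)
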