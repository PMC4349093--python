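"""Simulator: meiosis, cross families, selection, field panels."""

import numpy as np
import pytest

from wcrmap.errors import DataError, ExtinctionError
from wcrmap.markers import HEMI, MISSING
from wcrmap.simcross import (CrossConfig, FieldPanelConfig, FitnessModel, ParentGenome,
                             _gametes_from_pairs, make_sim_map, simulate_cross_family,
                             simulate_field_panel, simulate_gamete)
from wcrmap.fieldval import scores_from_table

from conftest import tiny_map, two_autosome_map


class TestGametes:
    def test_homozygous_parent_gamete_identical_to_haplotype(self, small_map):
        haps = {"LG1": np.zeros((2, 4), dtype=np.int8), "X": np.ones((2, 2), dtype=np.int8)}
        parent = ParentGenome("F", haps)
        rng = np.random.default_rng(0)
        g = simulate_gamete(parent, small_map, rng)
        assert np.array_equal(g["LG1"], np.zeros(4))
        assert np.array_equal(g["X"], np.ones(2))

    def test_zero_distance_complete_linkage(self):
        rng = np.random.default_rng(1)
        haps = np.broadcast_to(np.array([[0], [1]], np.int8), (10000, 2, 2)).copy()
        g = _gametes_from_pairs(haps, np.array([5.0, 5.0]), rng)
        assert np.all(g[:, 0] == g[:, 1])  # recombinant fraction exactly 0

    def test_recombinant_fraction_matches_haldane(self):
        # 20 cM under no interference: r = (1 - exp(-0.4))/2 = 0.16484
        rng = np.random.default_rng(2)
        n = 100_000
        haps = np.broadcast_to(np.array([[0], [1]], np.int8), (n, 2, 2)).copy()
        g = _gametes_from_pairs(haps, np.array([0.0, 20.0]), rng)
        r_obs = np.mean(g[:, 0] != g[:, 1])
        r_true = 0.5 * (1 - np.exp(-0.4))
        se = np.sqrt(r_true * (1 - r_true) / n)
        assert abs(r_obs - r_true) < 3 * se

    def test_male_parent_transmits_single_x_without_recombination(self, small_map):
        haps = {"LG1": np.zeros((2, 4), dtype=np.int8),
                "X": np.array([[0, 1]], dtype=np.int8)}
        parent = ParentGenome("M", haps)
        rng = np.random.default_rng(3)
        g = simulate_gamete(parent, small_map, rng, include_x=True)
        assert np.array_equal(g["X"], [0, 1])
        assert simulate_gamete(parent, small_map, rng, include_x=False)["X"] is None

    def test_unmapped_marker_errors(self, small_map):
        parent = ParentGenome("F", {"LG1": np.zeros((2, 3), dtype=np.int8),
                                    "X": np.zeros((2, 2), dtype=np.int8)})
        with pytest.raises(DataError):
            simulate_gamete(parent, small_map, np.random.default_rng(0))


class TestCrossFamily:
    def test_mendelian_consistency_and_xo_bookkeeping(self, small_map, clean_config,
                                                      recessive_fitness):
        fam = simulate_cross_family(clean_config, small_map, recessive_fitness)
        p_calls = fam.parents.calls
        x_cols = [fam.parents.marker_index(m) for m in ("X0", "X1")]
        for gm in (fam.f1, fam.f2_treatment, fam.f2_control):
            males = (gm.individuals["sex"] == "M").to_numpy()
            for j in range(gm.n_markers):
                parental = {a for a in p_calls[:, j, :].ravel() if a >= 0}
                called = gm.calls[:, j, :]
                assert set(called[called >= 0].ravel()) <= parental
            for j in x_cols:
                assert np.all(gm.calls[males, j, 1] == HEMI)
                assert np.all(gm.calls[~males, j, 1] != HEMI)
            for j in range(gm.n_markers):
                if j not in x_cols:
                    assert np.all(gm.calls[:, j, 1] != HEMI)

    def test_no_selection_treatment_matches_control(self, small_map):
        # with flat fitness, treatment-vs-control causal tables should be null
        from wcrmap.scan import chisq_independence
        flat = FitnessModel(1.0, 1.0, resistance_marker_id="A2")
        nonsig = 0
        n_runs = 100
        for s in range(n_runs):
            cfg = CrossConfig(n_families=1, n_f1=30, n_f2_treatment=200,
                              n_f2_control=200, genotyping_error_rate=0.0,
                              missing_rate=0.0, seed=s)
            fam = simulate_cross_family(cfg, tiny_map(), flat)
            t = np.bincount(fam.truth_causal["f2_treatment"], minlength=3)
            c = np.bincount(fam.truth_causal["f2_control"], minlength=3)
            _, _, p = chisq_independence(np.vstack([t, c]))
            nonsig += p >= 0.05
        assert nonsig >= 0.94 * n_runs

    def test_full_selection_only_rr_survives(self, small_map, clean_config):
        lethal = FitnessModel(0.0, 0.0, resistance_marker_id="A2")
        fam = simulate_cross_family(clean_config, small_map, lethal)
        assert np.all(fam.truth_causal["f2_treatment"] == 2)

    def test_recessive_survivor_proportions(self, small_map):
        # normalize (0.25*0, 0.5*0.036, 0.25*1) -> (0, 0.0672, 0.9328)
        cfg = CrossConfig(n_families=1, n_f1=40, n_f2_treatment=2000,
                          n_f2_control=100, genotyping_error_rate=0.0,
                          missing_rate=0.0, seed=5)
        fam = simulate_cross_family(cfg, small_map,
                                    FitnessModel(0.0, 0.036, resistance_marker_id="A2"))
        counts = np.bincount(fam.truth_causal["f2_treatment"], minlength=3)
        n = counts.sum()
        assert n >= 400
        expected = np.array([0.0, 0.5 * 0.036, 0.25]) / (0.5 * 0.036 + 0.25)
        for k in range(3):
            se = np.sqrt(max(expected[k] * (1 - expected[k]), 1e-12) / n)
            assert abs(counts[k] / n - expected[k]) <= 3 * se + 1e-9

    def test_selection_monotone_in_heterozygote_fitness(self, small_map):
        shares = []
        for w_rs in (0.1, 0.4, 0.8):
            cfg = CrossConfig(n_families=1, n_f1=40, n_f2_treatment=20000,
                              n_f2_control=100, genotyping_error_rate=0.0,
                              missing_rate=0.0, seed=9)
            fam = simulate_cross_family(
                cfg, small_map, FitnessModel(0.0, w_rs, resistance_marker_id="A2"))
            causal = fam.truth_causal["f2_treatment"]
            shares.append(np.mean(causal == 1))
        assert shares[0] < shares[1] < shares[2]

    def test_extinction_raises_naming_arm(self, small_map):
        lethal = FitnessModel(0.0, 0.0, resistance_marker_id="A2")
        raised = None
        for s in range(30):
            cfg = CrossConfig(n_families=1, n_f1=20, n_f2_treatment=2,
                              n_f2_control=50, seed=s,
                              genotyping_error_rate=0.0, missing_rate=0.0)
            try:
                simulate_cross_family(cfg, small_map, lethal)
            except ExtinctionError as exc:
                raised = exc
                break
        assert raised is not None and raised.arm == "treatment"
        assert "treatment" in str(raised)

    def test_noise_rates_applied(self, small_map, recessive_fitness):
        cfg = CrossConfig(n_families=1, n_f1=200, n_f2_treatment=400,
                          n_f2_control=400, genotyping_error_rate=0.0,
                          missing_rate=0.2, seed=13)
        fam = simulate_cross_family(cfg, small_map, recessive_fitness)
        frac_missing = np.mean(fam.f2_control.calls[:, :, 0] == MISSING)
        assert 0.15 < frac_missing < 0.25
        # parents stay noise-free
        assert np.all(fam.parents.calls[:, :, 0] != MISSING)

    def test_determinism_same_seed_same_output(self, small_map, recessive_fitness, tmp_path):
        from wcrmap.io import write_genotype_table
        cfg = CrossConfig(n_families=1, n_f1=30, n_f2_treatment=100,
                          n_f2_control=100, seed=21)
        paths = []
        for k in range(2):
            fam = simulate_cross_family(cfg, small_map, recessive_fitness,
                                        rng=np.random.default_rng(cfg.seed))
            p = tmp_path / f"run{k}.tsv"
            write_genotype_table(fam.to_genotype_matrix(), p, "simulate-cross", 21, "x")
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestControlSegregation:
    def test_control_genotypes_fit_1_2_1_across_seeds(self, small_map):
        """Goodness-of-fit p-values over seeds are uniform (KS, alpha=0.01)."""
        from scipy import stats
        from wcrmap.scan import goodness_of_fit
        fm = FitnessModel(1.0, 1.0, resistance_marker_id="A2")
        pvals = []
        for s in range(200):
            cfg = CrossConfig(n_families=1, n_f1=30, n_f2_treatment=10,
                              n_f2_control=150, genotyping_error_rate=0.0,
                              missing_rate=0.0, seed=s)
            fam = simulate_cross_family(cfg, small_map, fm)
            counts = np.bincount(fam.truth_causal["f2_control"], minlength=3)
            _, _, p = goodness_of_fit(counts, (1, 2, 1))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFieldPanel:
    def test_fixed_high_frequency_scores_near_one(self):
        cfg = FieldPanelConfig(n_populations=40, beta_a=1e9, beta_b=1e-3,
                               baseline_survival=0.5, seed=0)
        _, bio = simulate_field_panel(cfg, ["CRW1683"])
        scores = scores_from_table(bio, "plant")["score"]
        assert abs(scores.mean() - 1.0) < 0.05

    def test_zero_frequency_zero_w_ss_scores_zero(self):
        cfg = FieldPanelConfig(n_populations=20, beta_a=1e-9, beta_b=1.0,
                               w_ss=0.0, seed=1)
        _, bio = simulate_field_panel(cfg, ["CRW1683"])
        scores = scores_from_table(bio, "plant")["score"]
        assert np.allclose(scores, 0.0)

    def test_replicate_structure(self):
        cfg = FieldPanelConfig(n_populations=5, seed=2)
        freq, bio = simulate_field_panel(cfg, ["m1", "m2"])
        plant = bio[bio["assay_type"] == "plant"]
        diet = bio[bio["assay_type"] == "diet"]
        assert len(plant) == 5 * cfg.plant_replicates
        assert len(diet) == 5 * cfg.diet_plates
        assert (plant["n_exposed"] == cfg.plant_larvae).all()
        assert (diet["n_exposed"] == cfg.diet_wells).all()
        assert len(freq) == 10 and freq["n_genotyped"].eq(48).all()

    def test_determinism(self):
        cfg = FieldPanelConfig(n_populations=10, seed=3)
        a = simulate_field_panel(cfg, ["m1"])
        b = simulate_field_panel(cfg, ["m1"])
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_invalid_beta_parameters(self):
        with pytest.raises(DataError):
            FieldPanelConfig(beta_a=0.0)


class TestFitnessModelValidation:
    def test_w_rr_is_fixed_reference(self):
        with pytest.raises(DataError):
            FitnessModel(0.1, 0.2, resistance_marker_id="A0", w_rr=0.9)

    def test_fitness_bounds(self):
        with pytest.raises(DataError):
            FitnessModel(-0.1, 0.2, resistance_marker_id="A0")

    def test_x_linked_causal_rejected(self, small_map, clean_config):
        fm = FitnessModel(0.0, 0.1, resistance_marker_id="X0")
        with pytest.raises(DataError):
            simulate_cross_family(clean_config, small_map, fm)


def test_default_map_shape():
    m = make_sim_map()
    assert len(m.groups) == 10
    assert m.n_markers == 1150
    assert sum(g.is_x for g in m.groups) == 1
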