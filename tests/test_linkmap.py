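"""Two-point estimation, map functions, grouping, ordering, merging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wcrmap.errors import DataError
from wcrmap.linkmap import (LinkageMap, MapGroup, estimate_rec_fraction, group_markers,
                            haldane_cm, haldane_inverse, kosambi_cm, kosambi_inverse,
                            linkages_from_matrices, map_summary, merge_maps, order_rcd,
                            pairwise_linkage_matrix, sarf, suggest_grouping_lod,
                            summary_from_counts, PairwiseLinkage)
from wcrmap.markers import MISSING, CodedMatrix

from conftest import simulate_coded_backcross, simulate_coded_intercross


class TestMapFunctions:
    def test_kosambi_values(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.2) == pytest.approx(21.18, abs=0.01)

    def test_kosambi_inverse_identity(self):
        for r in (0.0, 0.05, 0.2, 0.37, 0.49):
            assert kosambi_inverse(kosambi_cm(r)) == pytest.approx(r, abs=1e-12)

    def test_haldane_inverse_identity(self):
        for r in (0.0, 0.05, 0.2, 0.37, 0.49):
            assert haldane_inverse(haldane_cm(r)) == pytest.approx(r, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DataError):
            kosambi_cm(0.5)
        with pytest.raises(DataError):
            kosambi_inverse(-1.0)
        with pytest.raises(DataError):
            haldane_cm(0.6)


def _independent_f2_loglik(counts9, r):
    """Likelihood oracle built from first principles: enumerate gamete pairs."""
    gam = {(0, 0): (1 - r) / 2, (1, 1): (1 - r) / 2, (0, 1): r / 2, (1, 0): r / 2}
    probs = np.zeros(9)
    for g1, p1 in gam.items():
        for g2, p2 in gam.items():
            i, j = g1[0] + g2[0], g1[1] + g2[1]
            probs[i * 3 + j] += p1 * p2
    with np.errstate(divide="ignore"):
        return float(np.sum(np.where(counts9 > 0, counts9 * np.log(probs + 1e-300), 0.0)))


class TestRecFraction:
    def test_backcross_closed_form(self):
        c1 = np.array([0] * 90 + [0] * 10, dtype=np.int8)
        c2 = np.array([0] * 90 + [1] * 10, dtype=np.int8)
        pl = estimate_rec_fraction(c1, c2, design="backcross")
        assert pl.r_hat == pytest.approx(0.10)
        assert pl.lod == pytest.approx(15.98, abs=0.01)
        assert pl.n_informative == 100

    def test_backcross_no_linkage(self):
        c1 = np.array([0, 1] * 50, dtype=np.int8)
        c2 = np.array([0] * 50 + [1] * 50, dtype=np.int8)
        pl = estimate_rec_fraction(c1, c2, design="backcross")
        assert pl.r_hat == 0.5 and pl.lod == pytest.approx(0.0, abs=1e-9)

    def test_backcross_phase_unknown_folds(self):
        c1 = np.array([0] * 90 + [0] * 10, dtype=np.int8)
        c2 = np.array([1] * 90 + [0] * 10, dtype=np.int8)  # repulsion arrangement
        pl = estimate_rec_fraction(c1, c2, design="backcross", phase_known=False)
        assert pl.r_hat == pytest.approx(0.10)

    def test_too_few_informative(self):
        with pytest.raises(DataError):
            estimate_rec_fraction(np.array([0], dtype=np.int8),
                                  np.array([1], dtype=np.int8), design="backcross")

    def test_f2_em_matches_grid_oracle_and_truth(self):
        rng = np.random.default_rng(42)
        codes = simulate_coded_intercross([0.0, haldane_cm(0.2)], 2000, rng)
        pl = estimate_rec_fraction(codes[:, 0], codes[:, 1], design="F2_intercross")
        se = np.sqrt(0.2 * 0.8 / (2 * 2000))
        assert abs(pl.r_hat - 0.2) < 3 * se
        counts9 = np.zeros(9)
        np.add.at(counts9, codes[:, 0] * 3 + codes[:, 1], 1.0)
        grid = np.arange(0.0001, 0.5, 0.0001)
        lls = [_independent_f2_loglik(counts9, r) for r in grid]
        r_grid = grid[int(np.argmax(lls))]
        assert abs(pl.r_hat - r_grid) <= 1e-4 + 1e-6  # grid resolution + EM tolerance

    def test_estimator_consistency_both_designs(self):
        """Mean bias below 0.01 at n=2000 for a range of true r values."""
        rng = np.random.default_rng(7)
        for r_true in (0.05, 0.1, 0.2, 0.3):
            d = haldane_cm(r_true)
            for design, sim in (("backcross", simulate_coded_backcross),
                                ("F2_intercross", simulate_coded_intercross)):
                est = []
                for _ in range(40):
                    codes = sim([0.0, d], 2000, rng)
                    est.append(estimate_rec_fraction(codes[:, 0], codes[:, 1],
                                                     design=design).r_hat)
                assert abs(np.mean(est) - r_true) < 0.01


class TestGrouping:
    def test_no_linkage_all_singletons(self):
        pls = [PairwiseLinkage(("a", "b"), 0.5, 0.0, 100),
               PairwiseLinkage(("b", "c"), 0.5, 0.0, 100),
               PairwiseLinkage(("a", "c"), 0.5, 0.0, 100)]
        assert group_markers(pls) == [["a"], ["b"], ["c"]]

    def test_transitive_chain(self):
        pls = [PairwiseLinkage(("a", "b"), 0.1, 10.0, 100),
               PairwiseLinkage(("b", "c"), 0.1, 10.0, 100),
               PairwiseLinkage(("a", "c"), 0.5, 0.0, 100)]
        assert group_markers(pls) == [["a", "b", "c"]]

    def test_panel_group_recovery(self):
        """A dense 10-group panel (~300 markers, n=200) groups into 10 in >=95% of seeds."""
        positions = np.linspace(0.0, 230.0, 30)
        hits = 0
        n_seeds = 50
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            blocks = [simulate_coded_intercross(positions, 200, rng) for _ in range(9)]
            blocks.append(simulate_coded_backcross(positions, 200, rng))
            designs = ["F2_intercross"] * 9 + ["backcross"]
            all_links = []
            mids_all = []
            for k, (codes, design) in enumerate(zip(blocks, designs)):
                mids = [f"g{k:02d}_{i:02d}" for i in range(codes.shape[1])]
                mids_all.extend(mids)
                cm = CodedMatrix(pd.DataFrame({"id": range(200)}), mids, codes, design)
                all_links.append(pairwise_linkage_matrix(cm))
            # combine into genome-wide matrices (cross-block pairs unlinked: simulate)
            m = len(mids_all)
            r = np.full((m, m), np.nan)
            lod = np.zeros((m, m))
            off = 0
            rng2 = np.random.default_rng(1000 + s)
            for k, (r_df, lod_df, _) in enumerate(all_links):
                w = r_df.shape[0]
                r[off:off + w, off:off + w] = r_df.to_numpy()
                lod[off:off + w, off:off + w] = lod_df.to_numpy()
                off += w
            # cross-block estimates: unlinked backcross counts at n=200
            iu = np.triu_indices(m, 1)
            for i, j in zip(*iu):
                if np.isnan(r[i, j]):
                    c = min(rng2.binomial(200, 0.5), 200 - rng2.binomial(0, 0))
                    c = min(c, 200 - c)
                    r[i, j] = r[j, i] = c / 200
                    n_p, n_r = 200 - c, c
                    lod[i, j] = lod[j, i] = max(
                        n_p * np.log10(2 * (1 - c / 200)) + n_r * np.log10(2 * c / 200)
                        if c > 0 else 200 * np.log10(2), 0.0)
            r_df = pd.DataFrame(r, index=mids_all, columns=mids_all)
            lod_df = pd.DataFrame(lod, index=mids_all, columns=mids_all)
            n_df = pd.DataFrame(np.full((m, m), 200), index=mids_all, columns=mids_all)
            groups = group_markers(linkages_from_matrices(r_df, lod_df, n_df),
                                   lod_min=suggest_grouping_lod(m), r_max=0.35)
            hits += len(groups) == 10
        assert hits >= 0.95 * n_seeds


class TestOrdering:
    def test_two_marker_positions(self):
        r = pd.DataFrame([[0.0, 0.1], [0.1, 0.0]], index=["m1", "m2"], columns=["m1", "m2"])
        order, pos = order_rcd(["m1", "m2"], r)
        assert order == ["m1", "m2"]
        assert pos[1] == pytest.approx(25 * np.log(1.2 / 0.8), abs=1e-9)
        assert pos[1] == pytest.approx(10.14, abs=0.01)

    def test_equal_r_gives_lexicographic_chain(self):
        mids = ["d", "b", "a", "c"]
        r = pd.DataFrame(0.2 * (1 - np.eye(4)), index=mids, columns=mids)
        order, _ = order_rcd(mids, r)
        assert order == ["a", "b", "c", "d"]

    def test_matches_exhaustive_sarf_minimizer(self):
        """RCD order equals the global SARF optimum on simulated 4-marker groups."""
        agree = 0
        for s in range(12):
            rng = np.random.default_rng(100 + s)
            positions = np.sort(rng.uniform(0, 50, 4))
            codes = simulate_coded_intercross(positions, 1000, rng)
            mids = [f"m{i}" for i in range(4)]
            cm = CodedMatrix(pd.DataFrame({"id": range(1000)}), mids, codes,
                             "F2_intercross")
            r_df, _, _ = pairwise_linkage_matrix(cm)
            order, _ = order_rcd(mids, r_df)
            best = min((tuple(p) for p in itertools.permutations(mids)),
                       key=lambda p: (sarf(list(p), r_df), p))
            canonical = order if order[0] <= order[-1] else order[::-1]
            best = best if best[0] <= best[-1] else best[::-1]
            agree += tuple(canonical) == tuple(best)
        assert agree == 12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        positions = np.sort(rng.uniform(0, 40, 5))
        codes = simulate_coded_backcross(positions, 800, rng)
        mids = [f"m{i}" for i in range(5)]
        cm = CodedMatrix(pd.DataFrame({"id": range(800)}), mids, codes, "backcross")
        r_df, _, _ = pairwise_linkage_matrix(cm)
        ref_order, ref_pos = order_rcd(mids, r_df)
        perm = ["m3", "m0", "m4", "m2", "m1"]
        order2, pos2 = order_rcd(perm, r_df)
        assert order2 == ref_order
        assert np.allclose(pos2, ref_pos)

    def test_missing_pair_estimate_errors(self):
        r = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]],
                         index=["m1", "m2"], columns=["m1", "m2"])
        with pytest.raises(DataError):
            order_rcd(["m1", "m2"], r)

    def test_positions_strictly_increase_with_positive_r(self):
        rng = np.random.default_rng(11)
        positions = np.linspace(0, 60, 6)
        codes = simulate_coded_intercross(positions, 500, rng)
        mids = [f"m{i}" for i in range(6)]
        cm = CodedMatrix(pd.DataFrame({"id": range(500)}), mids, codes, "F2_intercross")
        r_df, _, _ = pairwise_linkage_matrix(cm)
        _, pos = order_rcd(mids, r_df)
        assert np.all(np.diff(pos) > 0)


class TestMerging:
    def _map(self, mids, positions, gid="G1", provenance="comp"):
        return LinkageMap([MapGroup(gid, mids, np.asarray(positions, float))],
                          provenance=provenance)

    def test_self_merge_idempotent(self):
        lm = self._map(["a", "b", "c"], [0.0, 10.0, 25.0])
        merged = merge_maps([lm, lm])
        assert merged.groups[0].marker_ids == ["a", "b", "c"]
        assert np.allclose(merged.groups[0].positions_cm, [0.0, 10.0, 25.0], atol=1e-9)

    def test_monotone_rescaling_preserves_order(self):
        a = self._map(["a", "b", "c", "d"], [0.0, 10.0, 20.0, 30.0])
        b = self._map(["a", "b", "c", "d"], [0.0, 20.0, 40.0, 60.0])
        merged = merge_maps([a, b])
        assert merged.groups[0].marker_ids == ["a", "b", "c", "d"]

    def test_too_few_anchors_errors(self):
        a = self._map(["a", "b", "c"], [0, 10, 20])
        b = self._map(["c", "x", "y"], [0, 10, 20], gid="G9")
        with pytest.raises(DataError):
            merge_maps([a, b])

    def test_conflicting_group_assignment_errors(self):
        a = LinkageMap([MapGroup("G1", ["a", "b", "m"], np.array([0.0, 5.0, 10.0])),
                        MapGroup("G2", ["x", "y"], np.array([0.0, 5.0]))])
        b = LinkageMap([MapGroup("G1", ["a", "b"], np.array([0.0, 5.0])),
                        MapGroup("G2", ["x", "y", "m"], np.array([0.0, 5.0, 10.0]))])
        with pytest.raises(DataError):
            merge_maps([a, b])

    def test_composite_order_recovers_truth(self):
        """Three component maps from one truth merge with Kendall tau >= 0.9."""
        taus = []
        positions = np.linspace(0.0, 100.0, 12)
        truth = [f"m{i:02d}" for i in range(12)]
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            maps = []
            for _ in range(3):
                codes = simulate_coded_intercross(positions, 200, rng)
                cm = CodedMatrix(pd.DataFrame({"id": range(200)}), truth, codes,
                                 "F2_intercross")
                r_df, _, _ = pairwise_linkage_matrix(cm)
                order, pos = order_rcd(truth, r_df)
                maps.append(LinkageMap([MapGroup("G1", order, pos)]))
            merged = merge_maps(maps)
            got = merged.groups[0].marker_ids
            tau = stats.kendalltau(range(12), [truth.index(m) for m in got]).statistic
            taus.append(abs(tau))
        assert np.median(taus) >= 0.9


class TestSummary:
    def test_study_scale_arithmetic(self):
        s = summary_from_counts(770, 10, 2325.0)
        assert s.mean_spacing_cm == 3.1

    def test_single_group(self):
        lm = LinkageMap([MapGroup("G1", ["a", "b"], np.array([0.0, 10.0]))])
        s = map_summary(lm)
        assert (s.n_groups, s.n_markers, s.span_cm, s.mean_spacing_cm) == (1, 2, 10.0, 10.0)

    def test_two_groups(self):
        lm = LinkageMap([MapGroup("G1", ["a", "b"], np.array([0.0, 4.0])),
                         MapGroup("G2", ["c", "d"], np.array([0.0, 6.0]))])
        s = map_summary(lm)
        assert s.span_cm == 10.0 and s.mean_spacing_cm == 5.0

    def test_singleton_group_excluded_with_warning(self):
        lm = LinkageMap([MapGroup("G1", ["a", "b"], np.array([0.0, 10.0])),
                         MapGroup("G2", ["c"], np.array([0.0]))])
        s = map_summary(lm)
        assert s.n_groups == 2 and s.mean_spacing_cm == 10.0
        assert len(s.warnings) == 1
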