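"""The three dysregulation scores, rank aggregation, and the permutation
null. Independent oracles: scipy.stats.ttest_ind / pearsonr for the
elementary statistics, a naive sort-based implementation for aggregation."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mgdtnet import (MGDT, MGDTRecord, aggregate_ranks,
                     compute_triplet_scores, enumerate_mgdts,
                     build_tripartite_network, pearson_correlation,
                     permutation_significance, select_significant,
                     student_t_test)
from mgdtnet.simulate import SyntheticDesign, generate_catalog, generate_study

from conftest import make_study


class TestStudentT:
    def test_equal_means_give_t_zero_p_one(self):
        t, p = student_t_test([1, 2, 3], [3, 2, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_equal_means_p_one_by_convention(self):
        t, p = student_t_test([5, 5, 5], [5, 5, 5])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_p_zero(self):
        t, p = student_t_test([5, 5, 5], [7, 7, 7])
        assert p == 0.0
        assert t == -math.inf

    def test_separated_groups_reference_values(self):
        # pooled t with df = 4; scipy as the independent reference
        t, p = student_t_test([1, 2, 3], [4, 5, 6])
        ref = sps.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=True)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-4)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 9))
        b = rng.normal(loc=rng.normal(), size=rng.integers(2, 9))
        t, p = student_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)
        tw, pw = student_t_test(a, b, welch=True)
        refw = sps.ttest_ind(a, b, equal_var=False)
        assert tw == pytest.approx(refw.statistic, rel=1e-10)
        assert pw == pytest.approx(refw.pvalue, rel=1e-10)

    def test_undersized_group_is_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            student_t_test([1.0], [1, 2, 3])


class TestPearson:
    def test_identity_and_reflection(self):
        x = [1.0, 2.0, 3.5, 7.0]
        assert pearson_correlation(x, x) == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_worked_example(self):
        assert pearson_correlation([1, 2, 3, 4],
                                   [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_reports_zero(self, caplog):
        assert pearson_correlation([1, 1, 1], [1, 2, 3]) == 0.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_too_short_is_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            pearson_correlation([1, 2], [3, 4])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        assert pearson_correlation(x, y) == pytest.approx(
            sps.pearsonr(x, y).statistic, rel=1e-10)


def _records(rows):
    """Build records from (s_risk, s_p, s_pcc) rows."""
    out = []
    for i, (sr, sp_, sc) in enumerate(rows):
        out.append(MGDTRecord(triplet=MGDT(f"m{i}", f"g{i}", f"d{i}"),
                              s_risk=sr, s_p=sp_, s_pcc=sc))
    return out


def naive_final_scores(rows):
    """Independent oracle: explicit sort-based average ranks, then the
    (N - r + 1)/N transform, averaged over the three channels."""
    n = len(rows)

    def avg_ranks(values, descending):
        order = sorted(values, reverse=descending)
        ranks = []
        for v in values:
            positions = [i + 1 for i, o in enumerate(order) if o == v]
            ranks.append(sum(positions) / len(positions))
        return ranks

    r1 = avg_ranks([r[0] for r in rows], True)
    r2 = avg_ranks([r[1] for r in rows], False)
    r3 = avg_ranks([r[2] for r in rows], True)
    return [((n - a + 1) / n + (n - b + 1) / n + (n - c + 1) / n) / 3
            for a, b, c in zip(r1, r2, r3)]


class TestAggregateRanks:
    def test_hand_enumerated_example(self):
        recs = aggregate_ranks(_records([(0.9, 0.001, 1.2),
                                         (0.5, 0.2, 0.3),
                                         (0.1, 0.9, 0.05)]))
        assert [r.final_score for r in recs] == pytest.approx(
            [1.0, 2 / 3, 1 / 3])

    def test_single_record_scores_one(self):
        recs = aggregate_ranks(_records([(0.3, 0.5, 0.1)]))
        assert recs[0].final_score == 1.0

    def test_full_ties_give_equal_scores(self):
        recs = aggregate_ranks(_records([(0.5, 0.1, 0.7)] * 4))
        scores = {r.final_score for r in recs}
        assert len(scores) == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_naive_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        # coarse grid to provoke ties
        rows = [tuple(rng.choice([0.1, 0.2, 0.5, 0.9]) for _ in range(3))
                for _ in range(n)]
        recs = aggregate_ranks(_records(rows))
        assert [r.final_score for r in recs] == pytest.approx(
            naive_final_scores(rows))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(0, 1, allow_nan=False), st.floats(1e-6, 1, allow_nan=False),
        st.floats(0, 2, allow_nan=False)), min_size=1, max_size=12),
        st.integers(0, 11))
    def test_improving_any_channel_never_lowers_the_score(self, rows, idx):
        """Weak monotonicity: larger s_risk or s_pcc, or smaller s_p, for
        one record (others fixed) never decreases its final score."""
        idx = idx % len(rows)
        base = aggregate_ranks(_records(rows))[idx].final_score
        for pos, better in ((0, lambda v: v + 0.5), (1, lambda v: v / 2),
                            (2, lambda v: v + 0.5)):
            bumped = [list(r) for r in rows]
            bumped[idx][pos] = better(bumped[idx][pos])
            new = aggregate_ranks(
                _records([tuple(r) for r in bumped]))[idx].final_score
            assert new >= base - 1e-12

    def test_scores_stay_in_unit_interval(self):
        rng = np.random.default_rng(3)
        rows = [tuple(rng.random(3)) for _ in range(40)]
        recs = aggregate_ranks(_records(rows))
        assert all(0.0 < r.final_score <= 1.0 for r in recs)


class TestTripletScores:
    def test_s_p_is_the_product_of_the_two_p_values(self, toy_catalog,
                                                    toy_study):
        trips = enumerate_mgdts(build_tripartite_network(toy_catalog))
        recs = compute_triplet_scores(toy_study, toy_catalog, trips)
        for r in recs:
            assert r.s_p == pytest.approx(r.p_mrna * r.p_mirna)
            assert r.s_pcc == pytest.approx(abs(r.d_pcc - r.c_pcc))

    def test_identical_group_matrices_zero_s_pcc(self, toy_catalog):
        rng = np.random.default_rng(0)
        half_g = {g: list(rng.normal(size=3)) for g in ("g1", "g2", "g3")}
        half_m = {m: list(rng.normal(size=3)) for m in ("m1", "m2")}
        study = make_study({g: v + v for g, v in half_g.items()},
                           {m: v + v for m, v in half_m.items()}, 3, 3)
        trips = enumerate_mgdts(build_tripartite_network(toy_catalog))
        recs = compute_triplet_scores(study, toy_catalog, trips)
        assert all(r.s_pcc == 0.0 for r in recs)

    def test_extreme_correlation_flip_gives_s_pcc_two(self):
        from mgdtnet import InteractionCatalog
        cat = InteractionCatalog(disease_genes={"g": 1.0},
                                 mirna_targets={("m", "g")},
                                 drug_targets={("d", "g")})
        x = [1.0, 2.0, 3.0]
        study = make_study({"g": x + x}, {"m": x + x[::-1]}, 3, 3)
        recs = compute_triplet_scores(study, cat,
                                      [MGDT("m", "g", "d")])
        assert recs[0].d_pcc == pytest.approx(1.0)
        assert recs[0].c_pcc == pytest.approx(-1.0)
        assert recs[0].s_pcc == pytest.approx(2.0)

    def test_triplets_sharing_a_gene_share_s_risk(self, toy_catalog,
                                                  toy_study):
        trips = enumerate_mgdts(build_tripartite_network(toy_catalog))
        recs = compute_triplet_scores(toy_study, toy_catalog, trips)
        by_gene = {}
        for r in recs:
            by_gene.setdefault(r.triplet.gene, set()).add(r.s_risk)
        assert all(len(v) == 1 for v in by_gene.values())

    def test_missing_feature_lists_offenders(self, toy_catalog, toy_study):
        with pytest.raises(ValueError, match="mystery"):
            compute_triplet_scores(toy_study, toy_catalog,
                                   [MGDT("m1", "mystery", "d1")])

    def test_score_ranges(self, toy_catalog, toy_study):
        trips = enumerate_mgdts(build_tripartite_network(toy_catalog))
        recs = compute_triplet_scores(toy_study, toy_catalog, trips)
        for r in recs:
            assert 0.0 < r.s_p <= 1.0
            assert 0.0 <= r.s_pcc <= 2.0

    def test_small_group_rejected_unless_degenerate_allowed(self,
                                                            toy_catalog):
        rng = np.random.default_rng(1)
        study = make_study({g: list(rng.normal(size=5))
                            for g in ("g1", "g2", "g3")},
                           {m: list(rng.normal(size=5)) for m in ("m1", "m2")},
                           4, 1)
        trips = enumerate_mgdts(build_tripartite_network(toy_catalog))
        with pytest.raises(ValueError, match="control"):
            compute_triplet_scores(study, toy_catalog, trips)
        recs = compute_triplet_scores(study, toy_catalog, trips,
                                      allow_degenerate_groups=True)
        assert all(r.c_pcc == 0.0 for r in recs)


class TestPermutationNull:
    def test_label_invariant_data_gives_p_one(self, toy_catalog):
        # all samples identical: every permutation reproduces the observed
        study = make_study({g: [1.0 + i] * 6
                            for i, g in enumerate(("g1", "g2", "g3"))},
                           {m: [2.0] * 6 for m in ("m1", "m2")}, 3, 3)
        trips = enumerate_mgdts(build_tripartite_network(toy_catalog))
        recs = permutation_significance(study, toy_catalog, trips,
                                        n_perm=30, seed=0)
        assert all(r.perm_p == 1.0 for r in recs)

    def test_planted_extreme_signal_sits_at_the_add_one_floor(self):
        """One extreme triplet vs noise at n_perm = 999: the only permuted
        final scores reaching the observed one come from label assignments
        equal to the original split (or its mirror image), so perm_p equals
        the add-one floor 1/1000 plus one count per such draw. The expected
        count is derived independently by replaying the documented RNG
        consumption (one full permutation per iteration)."""
        design = SyntheticDesign(seed=7, n_genes=12, n_mirnas=12, n_drugs=12,
                                 edge_density_mg=0.3, edge_density_dg=0.3,
                                 n_disease=6, n_control=6, n_planted=1,
                                 delta=6.0, rho_disease=0.95,
                                 rho_control=-0.95)
        cat = generate_catalog(design)
        study, truth = generate_study(design, cat)
        trips = enumerate_mgdts(build_tripartite_network(cat))
        recs = permutation_significance(study, cat, trips, n_perm=999, seed=1)
        planted = next(r for r in recs if r.triplet in truth.planted)

        rng = np.random.default_rng(1)
        original = frozenset(range(6))
        n_identity = sum(
            frozenset(rng.permutation(12)[:6]) in (original,
                                                   frozenset(range(6, 12)))
            for _ in range(999))
        assert planted.perm_p == pytest.approx((1 + n_identity) / 1000)
        assert planted.perm_p >= 1 / 1000  # the attainable minimum

    def test_reproducible_for_a_seed(self, toy_catalog, toy_study):
        trips = enumerate_mgdts(build_tripartite_network(toy_catalog))
        a = permutation_significance(toy_study, toy_catalog, trips,
                                     n_perm=50, seed=9)
        b = permutation_significance(toy_study, toy_catalog, trips,
                                     n_perm=50, seed=9)
        assert [r.perm_p for r in a] == [r.perm_p for r in b]

    def test_perm_p_respects_add_one_bounds(self, toy_catalog, toy_study):
        trips = enumerate_mgdts(build_tripartite_network(toy_catalog))
        recs = permutation_significance(toy_study, toy_catalog, trips,
                                        n_perm=20, seed=2)
        for r in recs:
            assert 1 / 21 <= r.perm_p <= 1.0

    def test_few_distinct_assignments_warn_not_error(self, toy_catalog,
                                                     toy_study, caplog):
        trips = enumerate_mgdts(build_tripartite_network(toy_catalog))
        permutation_significance(toy_study, toy_catalog, trips,
                                 n_perm=100, seed=0)  # C(6,3) = 20 < 100
        assert any("with replacement" in r.message for r in caplog.records)

    def test_pooled_null_mode_runs_and_bounds_hold(self, toy_catalog,
                                                   toy_study):
        trips = enumerate_mgdts(build_tripartite_network(toy_catalog))
        recs = permutation_significance(toy_study, toy_catalog, trips,
                                        n_perm=50, seed=3, pooled=True)
        for r in recs:
            assert 0.0 < r.perm_p <= 1.0


class TestSelectSignificant:
    def test_no_signal_selects_nothing(self):
        recs = _records([(0.5, 0.5, 0.5)] * 3)
        for r in recs:
            r.perm_p = 1.0
        subset, frac = select_significant(recs)
        assert subset == [] and frac == 0.0

    def test_strict_inequality_at_the_boundary(self):
        recs = _records([(0.5, 0.5, 0.5)] * 4)
        for r, p in zip(recs, (0.01, 0.049, 0.05, 0.9)):
            r.perm_p = p
        subset, frac = select_significant(recs, alpha=0.05)
        assert len(subset) == 2
        assert frac == pytest.approx(0.5)

    def test_bh_adjustment_is_more_conservative(self):
        recs = _records([(0.5, 0.5, 0.5)] * 5)
        for r, p in zip(recs, (0.01, 0.02, 0.04, 0.5, 0.9)):
            r.perm_p = p
        raw, _ = select_significant(recs)
        adj, _ = select_significant(recs, bh_adjust=True)
        assert len(adj) <= len(raw)
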