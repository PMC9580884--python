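import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as hst
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from divcom import (ValidationError, anosim, bh_adjust, chi_square, permanova,
                    permdisp, wilcoxon_rank_sum)
from divcom.stats import _pseudo_f, _group_indices


class TestWilcoxon:
    def test_exact_small_sample(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_multisets_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [3, 2, 1]).p_value == pytest.approx(1.0)

    def test_strong_separation_exact(self):
        res = wilcoxon_rank_sum([10, 11, 12], [1, 2, 3])
        assert res.p_value == pytest.approx(2 / 20)

    def test_constant_data_warns(self, caplog):
        res = wilcoxon_rank_sum([5, 5], [5, 5, 5])
        assert res.p_value == 1.0
        assert res.warning

    def test_empty_sample_errors(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])


class TestChiSquare:
    def test_study_contingency_counts(self):
        # PO/IV therapy counts across the three diagnosis groups.
        res = chi_square([[9, 12, 10], [10, 14, 7]])
        assert res.statistic == pytest.approx(0.736, abs=5e-4)
        assert res.p_value == pytest.approx(
            scipy.stats.chi2.sf(res.statistic, df=2))

    def test_proportional_table_is_null(self):
        res = chi_square([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_2x2_no_continuity_correction(self):
        res = chi_square([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)

    def test_yates_toggle_reduces_statistic(self):
        plain = chi_square([[10, 0], [0, 10]])
        corrected = chi_square([[10, 0], [0, 10]], yates_2x2=True)
        assert corrected.statistic < plain.statistic

    def test_zero_margin_errors(self):
        with pytest.raises(ValidationError):
            chi_square([[0, 0], [5, 5]])

    def test_low_expected_flagged(self):
        assert chi_square([[1, 2], [2, 1]]).warning


def _two_group_labels(n1, n2):
    return ["A"] * n1 + ["B"] * n2


class TestPermanova:
    def test_enumeration_p_under_perfect_separation(self, make_euclidean):
        # All 20 distinct 3|3 splits: only the observed split and its mirror
        # attain F_obs, so the exact permutation p is 2/20 = 0.1 and the
        # Monte-Carlo estimate must match it within sampling error.
        D = make_euclidean([0.0, 0.1, 0.2, 100.0, 100.1, 100.2])
        labels = _two_group_labels(3, 3)
        res = permanova(D, labels, n_perm=9999, seed=0)
        d2 = np.asarray(D.data) ** 2
        f_obs = _pseudo_f(d2, _group_indices(labels))
        n_ge = 0
        for combo in itertools.combinations(range(6), 3):
            groups = [np.array(combo), np.array([i for i in range(6)
                                                 if i not in combo])]
            n_ge += _pseudo_f(d2, groups) >= f_obs - 1e-9
        p_exact = n_ge / 20
        assert p_exact == pytest.approx(0.1)
        se = np.sqrt(p_exact * (1 - p_exact) / 9999)
        assert abs(res.p_value - p_exact) <= 3 * se

    def test_statistic_matches_skbio(self, make_euclidean):
        rng = np.random.default_rng(8)
        D = make_euclidean(rng.normal(size=(12, 3)))
        labels = _two_group_labels(6, 6)
        ours = permanova(D, labels, n_perm=99, seed=1)
        theirs = skbio_permanova(D, grouping=labels, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"])

    def test_invariance_under_reordering_and_relabel(self, make_euclidean):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        ids = [f"s{i}" for i in range(10)]
        labels = np.array(_two_group_labels(5, 5))
        D1 = make_euclidean(pts, ids=ids)
        f1 = permanova(D1, labels, n_perm=9, seed=0).statistic
        order = rng.permutation(10)
        D2 = make_euclidean(pts[order], ids=[ids[i] for i in order])
        f2 = permanova(D2, labels[order], n_perm=9, seed=0).statistic
        f3 = permanova(D1, np.where(labels == "A", "Z", "Y"),
                       n_perm=9, seed=0).statistic
        assert f1 == pytest.approx(f2)
        assert f1 == pytest.approx(f3)

    def test_reproducible_given_seed(self, make_euclidean):
        D = make_euclidean(np.random.default_rng(2).normal(size=(10, 2)))
        labels = _two_group_labels(5, 5)
        a = permanova(D, labels, n_perm=199, seed=7)
        b = permanova(D, labels, n_perm=199, seed=7)
        assert a.p_value == b.p_value

    def test_group_size_validation(self, make_euclidean):
        D = make_euclidean([0.0, 1.0, 2.0])
        with pytest.raises(ValidationError):
            permanova(D, ["A", "A", "B"], n_perm=9)


class TestPermdisp:
    def test_detects_threefold_dispersion(self, make_euclidean):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (50, 2))
        b = rng.normal(0, 3, (50, 2))
        D = make_euclidean(np.vstack([a, b]))
        res = permdisp(D, _two_group_labels(50, 50), n_perm=999, seed=1)
        assert res.p_value <= 0.001

    def test_mirror_groups_null(self, make_euclidean):
        # identical dispersion structure: rejection should be rare
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, (20, 2))
            D = make_euclidean(np.vstack([a, -a]))
            res = permdisp(D, _two_group_labels(20, 20), n_perm=99, seed=seed)
            rejections += res.p_value <= 0.05
        assert rejections <= 3

    def test_identical_points_degenerate(self, make_euclidean):
        D = DistanceMatrix(np.zeros((6, 6)), ids=list("abcdef"))
        res = permdisp(D, _two_group_labels(3, 3), n_perm=99, seed=0)
        assert res.p_value == 1.0
        assert res.warning

    def test_spatial_median_center_runs(self, make_euclidean):
        rng = np.random.default_rng(4)
        D = make_euclidean(rng.normal(size=(16, 2)))
        res = permdisp(D, _two_group_labels(8, 8), n_perm=99, seed=0,
                       center="spatial_median")
        assert 0 < res.p_value <= 1

    def test_singleton_group_errors(self, make_euclidean):
        D = make_euclidean([0.0, 1.0, 2.0])
        with pytest.raises(ValidationError):
            permdisp(D, ["A", "B", "B"], n_perm=9)


class TestAnosim:
    def test_perfect_separation_r_one(self, make_euclidean):
        D = make_euclidean([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        res = anosim(D, _two_group_labels(3, 3), n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_from_definition_ranks(self, make_euclidean):
        pts = np.array([0.0, 3.0, 1.5, 2.0, 5.0, 4.0])
        D = make_euclidean(pts)
        labels = np.array(_two_group_labels(3, 3))
        res = anosim(D, labels, n_perm=9, seed=0)
        d = np.abs(pts[:, None] - pts[None, :])
        iu = np.triu_indices(6, 1)
        ranks = scipy.stats.rankdata(d[iu])
        within = labels[iu[0]] == labels[iu[1]]
        expected = (ranks[~within].mean() - ranks[within].mean()) / (len(ranks) / 2)
        assert res.statistic == pytest.approx(expected)

    def test_matches_skbio(self, make_euclidean):
        rng = np.random.default_rng(6)
        D = make_euclidean(rng.normal(size=(12, 2)))
        labels = _two_group_labels(6, 6)
        ours = anosim(D, labels, n_perm=99, seed=2)
        theirs = skbio_anosim(D, grouping=labels, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"])

    def test_null_mean_near_zero(self, make_euclidean):
        stats = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            D = make_euclidean(rng.normal(size=(12, 2)))
            labels = rng.permutation(_two_group_labels(6, 6))
            stats.append(anosim(D, labels, n_perm=9, seed=seed).statistic)
        assert abs(np.mean(stats)) < 0.1


class TestBhAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_out_of_range_errors(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(min_value=0, max_value=1), min_size=1,
                     max_size=12))
    def test_adjusted_at_least_raw_and_monotone(self, pvals):
        adjusted = bh_adjust(pvals)
        assert (adjusted >= np.asarray(pvals) - 1e-12).all()
        assert (adjusted <= 1 + 1e-12).all()
        order = np.argsort(pvals)
        sorted_adj = adjusted[order]
        assert all(b >= a - 1e-12 for a, b in zip(sorted_adj, sorted_adj[1:]))

    def test_matches_manual_step_up(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=9)
        m = len(p)
        order = np.argsort(p)
        manual = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            manual[order[rank]] = running
        np.testing.assert_allclose(bh_adjust(p), manual, atol=1e-12)
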