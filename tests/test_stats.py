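"""Statistics: contingency tests, ROC, Spearman with censoring, decay fits."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from arescore import (
    DecayTimeCourse,
    enrichment_at_threshold,
    fit_half_life,
    group_summary,
    roc_auc,
    score_distribution,
    spearman,
)
from arescore.stats import contingency_2x2

from _oracles import enumerate_tables, fisher_two_sided, pair_count_auc, rank_pearson


class TestContingency:
    def test_identical_groups_have_zero_phi(self):
        r = contingency_2x2(10, 10, 10, 10)
        assert r.phi == 0
        assert r.chi2_p == pytest.approx(1.0)

    def test_phi_closed_form(self):
        r = contingency_2x2(30, 10, 10, 30)
        assert r.phi == pytest.approx(800 / 1600)

    def test_perfect_association_fisher_by_enumeration(self):
        r = contingency_2x2(5, 0, 0, 5)
        assert r.fisher_p == pytest.approx(fisher_two_sided(5, 0, 0, 5))
        assert r.fisher_p == pytest.approx(2 / math.comb(10, 5))

    def test_fisher_matches_enumeration_exhaustively(self):
        for a, b, c, d in enumerate_tables(16):
            r = contingency_2x2(a, b, c, d)
            assert r.fisher_p == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-10)

    def test_fisher_matches_enumeration_on_random_larger_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.multinomial(int(rng.integers(4, 41)), [0.25] * 4)
            r = contingency_2x2(a, b, c, d)
            assert r.fisher_p == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-10)

    def test_swapping_rows_flips_phi_sign(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) + 1 for x in rng.integers(0, 30, size=4))
            assert contingency_2x2(a, b, c, d).phi == pytest.approx(
                -contingency_2x2(c, d, a, b).phi
            )
            assert abs(contingency_2x2(a, b, c, d).phi) <= 1

    def test_zero_margin_disables_chi2_but_not_fisher(self):
        r = enrichment_at_threshold([1.0, 2.0], [0.5, 1.5], thresh=10.0)
        assert r.chi2_p is None
        assert r.fisher_p == pytest.approx(1.0)

    def test_enrichment_table_orientation(self):
        r = enrichment_at_threshold([5, 5, 1], [1, 1, 5], thresh=4)
        assert (r.a, r.b, r.c, r.d) == (2, 1, 1, 2)
        assert r.phi > 0


class TestScoreDistribution:
    def test_unit_bins(self):
        df = score_distribution([0.5, 1.2, 1.7], [0, 1, 2])
        assert df["frequency"].tolist() == pytest.approx([1 / 3, 2 / 3])
        assert df["cumulative"].tolist() == pytest.approx([1 / 3, 1.0])

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            score_distribution([], [0, 1])

    def test_score_outside_edges_is_an_error(self):
        with pytest.raises(ValueError):
            score_distribution([-0.1, 0.5], [0, 1])
        with pytest.raises(ValueError):
            score_distribution([0.5, 1.0], [0, 1])

    def test_all_in_one_bin_and_open_last_edge(self):
        df = score_distribution([5, 6, 100], [0, 4, np.inf])
        assert df["frequency"].tolist() == [0.0, 1.0]


class TestRoc:
    def test_perfect_separation(self):
        assert roc_auc([2, 3], [0, 1]).auc == pytest.approx(1.0)

    def test_all_tied(self):
        assert roc_auc([1, 1], [1, 1]).auc == pytest.approx(0.5)

    def test_pair_counting_example(self):
        assert roc_auc([2, 1], [1, 0]).auc == pytest.approx(0.875)

    def test_curve_runs_from_origin_to_one_one_monotonically(self, rng):
        r = roc_auc(rng.normal(1, 1, 30), rng.normal(0, 1, 40))
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_auc_equals_mann_whitney_u_and_pair_counting(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(2, 25, size=2)
            # integer scores force plenty of ties
            pos = rng.integers(0, 8, size=n1).astype(float)
            neg = rng.integers(0, 8, size=n2).astype(float)
            auc = roc_auc(pos, neg).auc
            u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n2), abs=1e-12)
            assert auc == pytest.approx(pair_count_auc(pos, neg), abs=1e-12)

    def test_complement_symmetry(self, rng):
        pos = rng.integers(0, 5, size=15).astype(float)
        neg = rng.integers(0, 5, size=12).astype(float)
        assert roc_auc(pos, neg).auc + roc_auc(neg, pos).auc == pytest.approx(1.0)


class TestSpearman:
    def test_monotone_vectors(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        assert spearman(x, y) == pytest.approx(rank_pearson(x, y))

    def test_matches_rank_pearson_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.integers(0, 10, size=n).astype(float)
            y = rng.integers(0, 10, size=n).astype(float)
            rs = spearman(x, y)
            if math.isnan(rs):
                assert np.ptp(x) == 0 or np.ptp(y) == 0
            else:
                assert rs == pytest.approx(rank_pearson(x, y), abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(base)
        assert spearman(x, 3 * y + 7) == pytest.approx(base)

    def test_censored_values_rank_as_top_ties(self):
        # censored entries beat every measured value regardless of stored number
        x = [4.0, 3.0, 2.0, 1.0, 0.0]
        y = [10.0, 20.0, 240.0, 240.0, 240.0]
        cens = [False, False, True, True, True]
        expected = rank_pearson(x, [10.0, 20.0, 1e9, 1e9, 1e9])
        assert spearman(x, y, y_censored=cens) == pytest.approx(expected)

    def test_zero_rank_variance_is_nan(self):
        assert math.isnan(spearman([1, 1, 1], [1, 2, 3]))


class TestFitHalfLife:
    def test_exact_halving_recovers_sixty_minutes(self):
        tc = DecayTimeCourse([0, 30, 60, 120], [1.0, 2 ** -0.5, 0.5, 0.25])
        hl = fit_half_life(tc)
        assert not hl.censored
        assert hl.value == pytest.approx(60.0)

    def test_constant_abundance_is_censored(self):
        hl = fit_half_life(DecayTimeCourse([0, 30, 60, 120], [1, 1, 1, 1]))
        assert hl.censored
        assert str(hl) == ">240"

    def test_slow_decay_beyond_limit_is_censored(self):
        # true half-life 480 min > 240 limit
        t = np.array([0, 30, 60, 120])
        hl = fit_half_life(DecayTimeCourse(t, np.exp(-math.log(2) / 480 * t)))
        assert hl.censored

    def test_recovery_under_multiplicative_noise(self, rng):
        t = np.array([0.0, 30.0, 60.0, 120.0])
        for true_hl in (30.0, 60.0, 120.0):
            est = []
            for _ in range(100):
                y = np.exp(-math.log(2) / true_hl * t) * np.exp(rng.normal(0, 0.05, 4))
                y /= y[0]
                hl = fit_half_life(DecayTimeCourse(t, y))
                assert not hl.censored
                est.append(hl.value)
            assert abs(np.mean(est) - true_hl) / true_hl < 0.10

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            DecayTimeCourse([0, 30], [1.0, -0.5])
        with pytest.raises(ValueError):
            fit_half_life(DecayTimeCourse([0, 30], [1.0, 0.5]))
        with pytest.raises(ValueError):
            fit_half_life(DecayTimeCourse([30, 60, 120], [1.0, 0.5, 0.25]))


class TestGroupSummary:
    def test_two_constant_groups(self):
        df = group_summary([0, 0, 0, 1, 1, 1], ["a", "a", "a", "b", "b", "b"])
        assert df["mean"].tolist() == [0.0, 1.0]
        assert df.attrs["pooled_mean"] == 0.5

    def test_singleton_group_has_no_se_or_test(self):
        df = group_summary([1.0, 2.0, 3.0], ["a", "b", "b"])
        row = df[df["group"] == "a"].iloc[0]
        assert math.isnan(row["se"]) and math.isnan(row["t_p"])

    def test_recovers_generating_means(self, rng):
        mus = {"g1": 0.0, "g2": 2.0, "g3": -1.0}
        values, labels = [], []
        for g, mu in mus.items():
            v = rng.normal(mu, 1.0, size=50)
            values.extend(v)
            labels.extend([g] * 50)
        df = group_summary(values, labels)
        for _, row in df.iterrows():
            assert abs(row["mean"] - mus[row["group"]]) < 3 * row["se"] + 1e-9
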