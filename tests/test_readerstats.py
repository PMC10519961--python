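"""Reader-study statistics: rates, kappas, exact Wilcoxon, reference tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu
from statsmodels.stats.inter_rater import (aggregate_raters, cohens_kappa,
                                           fleiss_kappa as sm_fleiss)

from virthist import readerstats as rs


class TestConfusionAndRates:
    def test_perfect_calls(self):
        gold = np.array([1] * 10 + [0] * 14, dtype=bool)
        c = rs.confusion(gold, gold)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 14, 0, 0)
        rates = rs.rate_metrics(c)
        assert all(v == 1.0 for v in rates.values())

    def test_complement_calls(self):
        gold = np.array([1, 1, 0, 0], dtype=bool)
        c = rs.confusion(~gold, gold)
        assert c.tp == 0 and c.tn == 0

    def test_reconstructed_counts_give_published_rates(self):
        """tp=9, fn=1, tn=13, fp=1 at n=24 yields sens 0.90 / spec 0.93."""
        c = rs.ConfusionCounts(tp=9, fp=1, tn=13, fn=1)
        rates = rs.rate_metrics(c)
        assert rs.round_half_up(rates["sensitivity"]) == 0.90
        assert rs.round_half_up(rates["specificity"]) == 0.93

    def test_ppv_19_of_21(self):
        rates = rs.rate_metrics(rs.ConfusionCounts(tp=19, fp=2, tn=10, fn=1))
        assert rs.round_half_up(rates["ppv"]) == 0.90

    def test_zero_denominator_reported_missing(self):
        rates = rs.rate_metrics(rs.ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert rates["sensitivity"] is None
        assert rates["ppv"] is None

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            rs.confusion([0, 1, 2], [0, 1, 1])


class TestMeans:
    def test_breast_sensitivity_mean(self):
        vals = [{"s": v} for v in (0.9, 0.9, 1.0, 1.0, 1.0)]
        assert rs.round_half_up(rs.mean_over_raters(vals)["s"]) == 0.96

    def test_prostate_npv_mean_uses_unrounded_rates(self):
        """(12/16 + 10/11 + 12/15)/3 rounds to 0.82, not the pooled 0.81."""
        vals = [{"npv": 12 / 16}, {"npv": 10 / 11}, {"npv": 12 / 15}]
        assert rs.round_half_up(rs.mean_over_raters(vals)["npv"]) == 0.82
        pooled = (12 + 10 + 12) / (16 + 11 + 15)
        assert rs.round_half_up(pooled) == 0.81

    def test_single_rater_identity(self):
        assert rs.mean_over_raters([{"a": 0.7}])["a"] == 0.7

    def test_missing_rates_excluded(self):
        out = rs.mean_over_raters([{"a": 0.5}, {"a": None}])
        assert out["a"] == 0.5


class TestConsensus:
    def test_unanimous_matrix(self):
        m = np.tile([1, 0, 1], (5, 1)).astype(bool)
        assert np.array_equal(rs.consensus_calls(m), m[0])

    def test_majority_two_of_three(self):
        m = np.array([[1], [1], [0]], dtype=bool)
        assert rs.consensus_calls(m)[0]

    def test_tie_breaks_toward_malignant(self):
        m = np.array([[1], [0]], dtype=bool)
        assert rs.consensus_calls(m)[0]
        assert not rs.consensus_calls(m, tie_break=False)[0]


class TestCohenKappa:
    def test_identical_vectors(self):
        v = np.array([1, 0, 1, 0, 1], dtype=bool)
        assert rs.cohen_kappa(v, v) == 1.0

    def test_hand_worked_agreement_table(self):
        """[[10,2],[3,9]] at n=24: kappa = (19/24 - 0.5)/0.5."""
        a = np.array([0] * 12 + [1] * 12, dtype=bool)
        b = np.array([0] * 10 + [1] * 2 + [0] * 3 + [1] * 9, dtype=bool)
        expected = (19 / 24 - ((13 / 24) * (12 / 24) + (11 / 24) * (12 / 24))) \
            / (1 - ((13 / 24) * (12 / 24) + (11 / 24) * (12 / 24)))
        assert rs.cohen_kappa(a, b) == pytest.approx(expected)

    def test_matches_statsmodels(self, rng):
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        table = np.zeros((2, 2))
        for i, j in zip(a, b):
            table[i, j] += 1
        assert rs.cohen_kappa(a, b) == pytest.approx(cohens_kappa(table).kappa)

    def test_independent_raters_near_zero_in_expectation(self):
        rng = np.random.default_rng(0)
        vals = [rs.cohen_kappa(rng.integers(0, 2, 24), rng.integers(0, 2, 24))
                for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.05

    def test_constant_equal_raters_defined_as_one(self):
        v = np.ones(6, dtype=bool)
        assert rs.cohen_kappa(v, v) == 1.0

    @given(st.integers(0, 2 ** 12 - 1), st.integers(0, 2 ** 12 - 1))
    @settings(max_examples=60, deadline=None)
    def test_label_swap_invariance(self, abits, bbits):
        a = np.array([(abits >> i) & 1 for i in range(12)], dtype=bool)
        b = np.array([(bbits >> i) & 1 for i in range(12)], dtype=bool)
        try:
            k1 = rs.cohen_kappa(a, b)
        except ValueError:
            return
        assert rs.cohen_kappa(~a, ~b) == pytest.approx(k1)


class TestFleissKappa:
    def test_unanimous_five_raters(self):
        gold = np.array([1] * 10 + [0] * 14, dtype=bool)
        m = np.tile(gold, (5, 1))
        assert rs.fleiss_kappa(m) == 1.0

    def test_maximal_discordance_two_raters(self):
        m = np.array([[1, 0, 1, 0], [0, 1, 0, 1]], dtype=bool)
        assert rs.fleiss_kappa(m) == pytest.approx(-1.0)

    def test_hand_worked_three_raters_four_items(self):
        m = np.array([[1, 1, 0, 0],
                      [1, 0, 0, 1],
                      [1, 1, 0, 0]], dtype=bool)
        # direct formula evaluation
        counts = np.stack([(~m).sum(0), m.sum(0)], 1)
        p_i = ((counts ** 2).sum(1) - 3) / 6
        p_cat = counts.sum(0) / 12
        expected = (p_i.mean() - (p_cat ** 2).sum()) / (1 - (p_cat ** 2).sum())
        assert rs.fleiss_kappa(m) == pytest.approx(expected)

    def test_matches_statsmodels(self, rng):
        m = rng.integers(0, 2, size=(4, 12)).astype(bool)
        agg, _ = aggregate_raters(m.T.astype(int))
        assert rs.fleiss_kappa(m) == pytest.approx(sm_fleiss(agg))

    def test_label_swap_invariance(self, rng):
        m = rng.integers(0, 2, size=(3, 20)).astype(bool)
        assert rs.fleiss_kappa(~m) == pytest.approx(rs.fleiss_kappa(m))


class TestWilcoxonRightExact:
    def test_fully_separated_three_vs_three(self):
        assert rs.wilcoxon_right_exact([4, 5, 6], [1, 2, 3]) == pytest.approx(0.05)

    def test_least_extreme_single_pair(self):
        assert rs.wilcoxon_right_exact([1.0], [2.0]) == 1.0

    def test_matches_scipy_for_all_small_sizes(self):
        rng = np.random.default_rng(1)
        for m in range(1, 7):
            for n in range(1, 13 - m):
                x = rng.normal(size=m)
                y = rng.normal(size=n)
                ours = rs.wilcoxon_right_exact(x, y)
                ref = mannwhitneyu(x, y, alternative="greater",
                                   method="exact").pvalue
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_ties_refused(self):
        with pytest.raises(ValueError, match="ties"):
            rs.wilcoxon_right_exact([1, 2, 2], [3, 4, 5])

    def test_p_in_unit_interval_and_swap_symmetry(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=4)
        p = rs.wilcoxon_right_exact(x, y)
        p_swap = rs.wilcoxon_right_exact(y, x)
        assert 0 < p <= 1 and 0 < p_swap <= 1
        # the two right tails overlap exactly at the observed statistic
        assert p + p_swap > 1.0


class TestStainQuality:
    def _table(self, virtual_scores, frozen_scores):
        import pandas as pd
        rows = []
        for method, scores in (("virtual", virtual_scores),
                               ("frozen", frozen_scores)):
            for img, per_rater in enumerate(scores):
                for rater, s in enumerate(per_rater):
                    rows.append((method, "overall", f"{method}{img}", rater, s))
        return pd.DataFrame(rows, columns=["method", "metric", "image",
                                           "rater", "score"])

    def test_per_image_inter_rater_average(self):
        q = self._table([[2, 3, 4]], [[1, 1, 1]])
        out = rs.stain_quality_summary(q)
        v = out["per_image"].query("method == 'virtual'")["inter_rater_mean"]
        assert float(v.iloc[0]) == pytest.approx(3.0)

    def test_fully_separated_p_equals_enumeration(self):
        virtual = [[3, 3, 2], [3, 3, 3], [4, 3, 3], [4, 4, 3], [4, 4, 4]]
        frozen = [[1, 1, 1], [1, 1, 2], [1, 2, 2], [2, 2, 2], [2, 2, 3]]
        # per-image means are distinct within each group and fully separated
        q = self._table(virtual, frozen)
        out = rs.stain_quality_summary(q)
        from math import comb
        assert out["p_values"]["overall"] == pytest.approx(1 / comb(10, 5))

    def test_all_equal_scores_give_sem_zero_and_no_test(self):
        q = self._table([[2, 2, 2]] * 3, [[2, 2, 2]] * 3)
        out = rs.stain_quality_summary(q)
        assert np.allclose(out["per_rater"]["sem"].fillna(0), 0)
        assert out["p_values"]["overall"] is None  # all tied, test refused


class TestReferenceTables:
    def test_breast_mean_column(self):
        report = rs.concordance_report(rs.example_breast_table()).rounded()
        assert report["mean"] == {"sensitivity": 0.96, "specificity": 0.91,
                                  "ppv": 0.89, "npv": 0.97, "accuracy": 0.93}

    def test_breast_consensus_column(self):
        report = rs.concordance_report(rs.example_breast_table()).rounded()
        assert report["consensus"] == {"sensitivity": 1.0, "specificity": 0.93,
                                       "ppv": 0.91, "npv": 1.0, "accuracy": 0.96}

    def test_breast_fleiss_and_prevalence(self):
        report = rs.concordance_report(rs.example_breast_table()).rounded()
        assert report["fleiss_kappa"] == 1.0
        assert report["prevalence"] == 0.42

    def test_breast_cohen_kappa_column(self):
        report = rs.concordance_report(rs.example_breast_table()).rounded()
        assert report["cohen_kappa"] == [0.83, 0.75, 1.0, 0.83, 0.92]

    def test_prostate_mean_column(self):
        report = rs.concordance_report(rs.example_prostate_table()).rounded()
        assert report["mean"] == {"sensitivity": 0.87, "specificity": 0.94,
                                  "ppv": 0.97, "npv": 0.82, "accuracy": 0.90}

    def test_prostate_consensus_column(self):
        report = rs.concordance_report(rs.example_prostate_table()).rounded()
        assert report["consensus"] == {"sensitivity": 0.85, "specificity": 1.0,
                                       "ppv": 1.0, "npv": 0.80, "accuracy": 0.91}

    def test_prostate_prevalence(self):
        assert rs.example_prostate_table().prevalence == pytest.approx(20 / 32)
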