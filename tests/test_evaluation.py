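"""Diagnostic-evaluation statistics against independent oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rsnrspect import (
    confusion_metrics,
    mcnemar_compare,
    roc_analysis,
    subgroup_performance,
    summarize_cohort,
    two_sample_ttest,
    univariate_logistic,
)
from rsnrspect.evaluation import classify_at_cutoff, exact_mcnemar_p


def preds(n_pos_correct, n_pos, n_neg_correct, n_neg):
    """Prediction/label vectors with the stated confusion counts."""
    labels = ["TVD"] * n_pos + ["control"] * n_neg
    predictions = (
        ["positive"] * n_pos_correct
        + ["negative"] * (n_pos - n_pos_correct)
        + ["negative"] * n_neg_correct
        + ["positive"] * (n_neg - n_neg_correct)
    )
    return predictions, labels


def pairs_auc(scores, labels):
    """Brute-force all-pairs concordance with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == "TVD"] if y.dtype.kind == "U" else s[y]
    neg = s[y == "control"] if y.dtype.kind == "U" else s[~y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_all_correct(self):
        p, l = preds(5, 5, 7, 7)
        cm = confusion_metrics(p, l)
        assert cm.rounded() == (100, 100, 100)

    def test_accuracy_identity_property(self, rng):
        for _ in range(20):
            n_pos, n_neg = rng.integers(2, 40, 2)
            p, l = preds(rng.integers(0, n_pos + 1), n_pos, rng.integers(0, n_neg + 1), n_neg)
            cm = confusion_metrics(p, l)
            expect = (cm.sensitivity * n_pos + cm.specificity * n_neg) / (n_pos + n_neg)
            assert cm.accuracy == pytest.approx(expect)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            confusion_metrics(["positive", "negative"], ["TVD", "TVD"])


class TestRoc:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.3, 1.1, 1.2]
        labels = ["control"] * 3 + ["TVD"] * 2
        r = roc_analysis(scores, labels)
        assert r.auc == 1.0
        assert r.metrics_at_cutoff.rounded() == (100, 100, 100)

    def test_all_tied_scores_are_degenerate(self):
        r = roc_analysis([1.0] * 6, ["TVD"] * 3 + ["control"] * 3)
        assert r.auc == 0.5
        assert r.degenerate and r.optimal_cutoff is None

    def test_lower_positive_marker_auto_oriented(self):
        scores = [0.7, 0.8, 0.85, 1.0, 1.1, 1.2]
        labels = ["TVD"] * 3 + ["control"] * 3
        r = roc_analysis(scores, labels)
        assert r.orientation == "lower-positive"
        assert r.auc == 1.0
        # classification at the cutoff: strictly below is positive
        assert classify_at_cutoff([r.optimal_cutoff], r.optimal_cutoff, r.orientation)[0] == False  # noqa: E712

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_all_pairs_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 40))
        labels = np.array(["TVD", "control"])[rng.integers(0, 2, n)]
        if len(set(labels)) < 2:
            labels[:2] = ["TVD", "control"]
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        r = roc_analysis(scores, labels)
        oriented = scores if r.orientation == "higher-positive" else -scores
        assert r.auc == pytest.approx(pairs_auc(oriented, labels), abs=1e-12)

    def test_cutoff_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(12), np.zeros(18)].astype(bool)
        scores[labels] += 1.2
        r1 = roc_analysis(scores, labels)
        r2 = roc_analysis(np.exp(scores), labels)
        assert r1.auc == pytest.approx(r2.auc)
        c1 = classify_at_cutoff(scores, r1.optimal_cutoff, r1.orientation)
        c2 = classify_at_cutoff(np.exp(scores), r2.optimal_cutoff, r2.orientation)
        np.testing.assert_array_equal(c1, c2)


class TestTtest:
    def test_identical_groups(self):
        t, p = two_sample_ttest([3.0, 3.0, 3.0], [3.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_shifted_groups_match_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10.0
        t, p = two_sample_ttest(a, b)
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2  # equal n: pooled variance
        t_expect = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        assert t == pytest.approx(t_expect)
        assert p < 0.01
        assert p == pytest.approx(2 * stats.t.sf(abs(t_expect), 4))

    def test_welch_option(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 30.0, 50.0]
        t_pooled, _ = two_sample_ttest(a, b)
        t_welch, _ = two_sample_ttest(a, b, welch=True)
        assert t_pooled != t_welch


class TestMcnemar:
    def test_symmetric_discordance(self):
        assert exact_mcnemar_p(5, 5) == 1.0

    def test_worked_binomial_example(self):
        # b=10, c=2: p = 2 * (C(12,0)+C(12,1)+C(12,2)) / 2^12 = 158/4096
        assert exact_mcnemar_p(10, 2) == pytest.approx(158 / 4096)

    def test_full_enumeration_up_to_20_discordant(self):
        for n in range(0, 21):
            for b in range(n + 1):
                c = n - b
                if n == 0:
                    assert exact_mcnemar_p(b, c) == 1.0
                    continue
                oracle = 2.0 * sum(comb(n, k) for k in range(min(b, c) + 1)) / 2.0**n
                assert exact_mcnemar_p(b, c) == pytest.approx(min(1.0, oracle), abs=1e-12)

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(10, 2), (3, 7), (1, 1), (0, 5)]:
            table = [[0, b], [c, 0]]
            assert exact_mcnemar_p(b, c) == pytest.approx(
                float(sm_mcnemar(table, exact=True).pvalue)
            )

    def test_paired_comparison_counts(self):
        labels = ["TVD"] * 4 + ["control"] * 4
        p1 = ["positive", "positive", "negative", "positive", "negative", "negative", "positive", "negative"]
        p2 = ["positive", "negative", "positive", "positive", "negative", "positive", "negative", "negative"]
        res = mcnemar_compare(p1, p2, labels)
        assert res.sensitivity_discordant == (1, 1)
        assert res.specificity_discordant == (1, 1)

    def test_identical_predictions_flagged(self):
        labels = ["TVD"] * 3 + ["control"] * 3
        p = ["positive"] * 3 + ["negative"] * 3
        res = mcnemar_compare(p, p, labels)
        assert res.sensitivity_p == 1.0 and res.specificity_p == 1.0
        assert len(res.flags) == 2


class TestLogistic:
    def test_binary_predictor_matches_cross_product_ratio(self):
        # 2x2 layout: a=exposed positive, b=exposed negative, c, d
        a, b, c, d = 20, 10, 7, 25
        score = np.r_[np.ones(a + b), np.zeros(c + d)]
        labels = np.r_[
            np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)
        ].astype(bool)
        res = univariate_logistic(score, labels)
        assert res.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-4)

    def test_null_score_has_no_effect(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = np.r_[np.ones(41), np.zeros(61)].astype(bool)
            score = rng.permutation(rng.normal(size=102))
            res = univariate_logistic(score, labels)
            if res.p_value > 0.05 and 0.5 < res.odds_ratio < 2.0:
                hits += 1
        assert hits >= 18  # >= 90% of permutation seeds

    def test_negation_flips_odds_direction(self, rng):
        labels = np.r_[np.ones(40), np.zeros(60)].astype(bool)
        score = rng.normal(size=100) - 0.8 * labels  # lower in disease
        plain = univariate_logistic(score, labels)
        neg = univariate_logistic(score, labels, negate=True)
        assert plain.odds_ratio < 1.0 < neg.odds_ratio
        assert neg.negated

    def test_perfect_separation_flagged(self):
        labels = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        score = labels.astype(float) * 5.0
        res = univariate_logistic(score, labels)
        assert res.separated and res.odds_ratio is None


class TestSubgroups:
    def make_records(self):
        return pd.DataFrame(
            {
                "label": ["TVD", "TVD", "control", "control"],
                "age": [50.0, 60.0, 70.0, 80.0],
                "sex": ["M", "F", "M", "F"],
                "bmi": [24.0, 26.0, 28.0, 30.0],
                "rsnr": [0.7, 0.9, 1.0, 1.2],
            }
        )

    def test_median_split_ties_go_up(self):
        rec = self.make_records()
        out = subgroup_performance(rec, "age", {"rsnr": 0.95})
        assert list(out["n"]) == [2, 2]
        assert out.iloc[0]["subgroup"] == "age<65"

    def test_degenerate_subgroup_flagged(self):
        rec = self.make_records()
        rec["age"] = 60.0  # all identical: lower group empty
        out = subgroup_performance(rec, "age", {"rsnr": 0.95})
        assert (out["flag"] != "").any()

    def test_cell_format_is_sens_spec_acc(self):
        rec = self.make_records()
        out = subgroup_performance(rec, "sex", {"rsnr": 0.95})
        cell = out.loc[out.subgroup == "M", "rsnr"].item()
        assert cell == "100/100/100"


class TestSummary:
    def test_indicator_scores_give_unit_auc(self):
        rec = pd.DataFrame(
            {
                "label": ["TVD"] * 4 + ["control"] * 5,
                "sds": [1.0] * 4 + [0.0] * 5,
                "rsnr": [0.7] * 4 + [1.1] * 5,
            }
        )
        out = summarize_cohort(rec)
        assert (out["auc"] == 1.0).all()
        assert set(out["score"]) == {"sds", "rsnr"}

    def test_missing_summed_scores_are_skipped(self):
        rec = pd.DataFrame(
            {
                "label": ["TVD"] * 3 + ["control"] * 3,
                "snr_rest": [3.1, 3.0, 2.9, 3.2, 3.3, 3.0],
                "snr_stress": [2.0, 2.1, 2.2, 3.1, 3.2, 3.4],
                "rsnr": [0.65, 0.7, 0.76, 0.97, 0.97, 1.13],
            }
        )
        out = summarize_cohort(rec)
        assert list(out["score"]) == ["snr_rest", "snr_stress", "rsnr"]
        assert out.loc[out.score == "rsnr", "orientation"].item() == "lower-positive"
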