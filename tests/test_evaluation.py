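"""Metric battery, uncertainty analyses and McNemar comparison."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retiqa import (
    GOOD,
    POOR,
    compute_metrics,
    map_likert_to_binary,
    mcnemar_test,
    uncertainty_probability_correlation,
)
from retiqa.evaluation import (
    exclusion_curve,
    image_uncertainty,
    uncertainty_error_summary,
)


class TestLikertMapping:
    @pytest.mark.parametrize("grade,expected", [(1, GOOD), (2, GOOD), (3, POOR),
                                                (4, POOR), (5, POOR)])
    def test_one_two_good_rest_poor(self, grade, expected):
        assert map_likert_to_binary(grade) == expected

    @pytest.mark.parametrize("grade", [0, 6, -1, 2.5, "3"])
    def test_out_of_range_rejected(self, grade):
        with pytest.raises(ValueError):
            map_likert_to_binary(grade)


def _vectors_from_confusion(tp, fp, fn, tn):
    y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
    y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
    return np.array(y_true), np.array(y_pred)


class TestComputeMetrics:
    def test_contingency_example(self):
        y, pred = _vectors_from_confusion(tp=9, fp=3, fn=1, tn=7)
        m = compute_metrics(y, pred)
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.8182, abs=5e-5)

    def test_f1_is_harmonic_mean_of_reported_precision_and_recall(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            m = compute_metrics(y, pred)
            if math.isfinite(m.precision) and math.isfinite(m.recall) \
                    and m.precision + m.recall > 0:
                hm = 2 * m.precision * m.recall / (m.precision + m.recall)
                assert m.f1 == pytest.approx(hm, abs=1e-9)
                assert m.f1 <= min(m.precision, m.recall) * 2 / 1 + 1e-9

    def test_perfect_ranking_gives_unit_aucs(self):
        y = np.array([0, 0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        m = compute_metrics(y, (p >= 0.5).astype(int), p)
        assert m.auc_roc == 1.0
        assert m.auc_prc == 1.0

    def test_auc_roc_equals_pairwise_mann_whitney_oracle(self):
        """AUC-ROC equals the mean over (poor, good) pairs of the rank indicator.

        Brute-force O(n^2) oracle with ties counted 1/2, on 50 random
        instances including heavily tied score sets.
        """
        rng = np.random.default_rng(17)
        for trial in range(50):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            # quantised scores force ties
            p = np.round(rng.random(n), 1 if trial % 2 else 3)
            m = compute_metrics(y, (p >= 0.5).astype(int), p)
            pos = p[y == 1]
            neg = p[y == 0]
            pairs = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
                pos[:, None] == neg[None, :]
            ).sum()
            oracle = pairs / (len(pos) * len(neg))
            assert m.auc_roc == pytest.approx(oracle, abs=1e-12)

    def test_no_positive_examples_reports_not_available(self):
        y = np.zeros(10, dtype=int)
        pred = np.zeros(10, dtype=int)
        m = compute_metrics(y, pred, np.linspace(0, 1, 10))
        assert math.isnan(m.precision) and math.isnan(m.recall)
        assert math.isnan(m.auc_roc) and math.isnan(m.auc_prc)
        assert m.accuracy == 1.0  # accuracy stays defined


def _prediction_frame(u, correct, likert=None):
    """Minimal CF prediction frame with a single labelled category pattern."""
    n = len(u)
    frame = pd.DataFrame({
        "image_path": [f"img{i}.png" for i in range(n)],
        "visit_id": ["v1"] * n,
        "patient_id": ["p1"] * n,
    })
    for cat in ("contrast", "focus", "illumination", "shadow_reflection", "overall"):
        frame[f"likert_{cat}"] = pd.array(
            [1 if c else 5 for c in correct], dtype="Int64"
        )
        frame[f"decision_{cat}"] = [GOOD] * n  # correct iff likert good
        frame[f"p_{cat}"] = 0.2
        frame[f"u_{cat}"] = u
    return frame


class TestUncertaintySummary:
    def test_pooled_means_match_direct_arithmetic(self):
        frame = _prediction_frame(u=[0.1, 0.2, 0.4], correct=[True, True, False])
        out = uncertainty_error_summary(frame, "CF")
        assert out["correct"]["mean"] == pytest.approx(0.15)
        assert out["incorrect"]["mean"] == pytest.approx(0.4)
        # every (image, category) pair with a label is pooled
        assert out["correct"]["n"] + out["incorrect"]["n"] == 3 * 5

    def test_all_correct_leaves_incorrect_side_not_available(self):
        frame = _prediction_frame(u=[0.1, 0.2], correct=[True, True])
        out = uncertainty_error_summary(frame, "CF")
        assert out["incorrect"]["n"] == 0
        assert math.isnan(out["incorrect"]["mean"])


class TestExclusionCurve:
    def test_fraction_zero_reproduces_baseline(self):
        frame = _prediction_frame(u=[0.3, 0.1, 0.2, 0.05],
                                  correct=[False, True, True, True])
        out = exclusion_curve(frame, "CF", fractions=(0.0,))
        assert out[0.0] == pytest.approx(0.75)

    def test_oracle_uncertainty_reaches_perfect_accuracy(self):
        """With uncertainty = 1 iff wrong, accuracy is nondecreasing and hits
        1.0 once every erroneous image is excluded."""
        rng = np.random.default_rng(5)
        correct = rng.random(10) > 0.2
        frame = _prediction_frame(u=[0.0] * 10, correct=correct)
        oracle_u = (~correct).astype(float)
        fractions = (0.0, 0.1, 0.2, 0.3, 0.5)
        out = exclusion_curve(frame, "CF", fractions, scalar_uncertainty=oracle_u)
        accs = [out[q] for q in fractions]
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))
        n_wrong = int((~correct).sum())
        q_enough = n_wrong / len(correct)
        assert out[min(f for f in fractions if f >= q_enough)] == 1.0

    def test_constructed_two_error_case(self):
        correct = [True] * 8 + [False] * 2
        u = [0.01] * 8 + [0.9, 0.8]
        frame = _prediction_frame(u=u, correct=correct)
        out = exclusion_curve(frame, "CF", fractions=(0.2,))
        assert out[0.2] == 1.0

    def test_fraction_at_or_above_one_rejected(self):
        frame = _prediction_frame(u=[0.1, 0.2], correct=[True, True])
        with pytest.raises(ValueError):
            exclusion_curve(frame, "CF", fractions=(1.0,))

    def test_scalar_uncertainty_is_mean_over_categories(self):
        frame = _prediction_frame(u=[0.1, 0.3], correct=[True, True])
        assert np.allclose(image_uncertainty(frame, "CF"), [0.1, 0.3])


class TestUncertaintyProbabilityCorrelation:
    def test_constant_uncertainty_is_not_available(self):
        p = np.linspace(0, 1, 20)
        assert math.isnan(uncertainty_probability_correlation(p, np.full(20, 0.1)))

    def test_inverted_parabola_gives_strong_negative_r(self):
        p = np.linspace(0, 1, 41)
        u = 0.25 - (p - 0.5) ** 2
        assert uncertainty_probability_correlation(p, u) < -0.9

    def test_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(7)
        p = rng.random(100)
        u = rng.random(100)
        r = uncertainty_probability_correlation(p, u)
        e = np.abs(p - 0.5)
        manual = ((u - u.mean()) * (e - e.mean())).sum() / (
            np.sqrt(((u - u.mean()) ** 2).sum()) * np.sqrt(((e - e.mean()) ** 2).sum())
        )
        assert r == pytest.approx(manual, abs=1e-10)


def _decisions_with_discordance(b, c, n_extra=5):
    """Construct decision vectors with exactly b/c discordant pairs."""
    y = np.zeros(b + c + n_extra, dtype=int)
    a = y.copy()
    bb = y.copy()
    bb[:b] = 1  # A correct, B wrong
    a[b:b + c] = 1  # A wrong, B correct
    return a, bb, y


class TestMcNemar:
    def test_exact_two_sided_p_for_six_two(self):
        a, bb, y = _decisions_with_discordance(6, 2)
        res = mcnemar_test(a, bb, y)
        assert res.method == "exact"
        assert (res.b, res.c) == (6, 2)
        assert res.p_value == pytest.approx(0.2891, abs=5e-5)
        assert not res.significant

    def test_balanced_discordance_gives_p_one(self):
        a, bb, y = _decisions_with_discordance(4, 4)
        res = mcnemar_test(a, bb, y)
        assert res.p_value == 1.0

    def test_chi_square_branch_formula(self):
        a, bb, y = _decisions_with_discordance(20, 10)
        res = mcnemar_test(a, bb, y)
        assert res.method == "chi2"
        assert res.statistic == pytest.approx((20 - 10) ** 2 / 30)
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 1))

    def test_no_discordance_is_degenerate(self):
        a, bb, y = _decisions_with_discordance(0, 0)
        res = mcnemar_test(a, bb, y)
        assert res.method == "degenerate" and res.p_value == 1.0

    def test_exact_branch_matches_binomial_enumeration(self):
        """Exact p equals the doubled binomial tail for every b+c <= 12."""
        for n_disc in range(1, 13):
            for b in range(n_disc + 1):
                c = n_disc - b
                a, bb, y = _decisions_with_discordance(b, c)
                res = mcnemar_test(a, bb, y)
                tail = sum(
                    math.comb(n_disc, k) for k in range(min(b, c) + 1)
                ) / 2 ** n_disc
                assert res.p_value == pytest.approx(min(1.0, 2 * tail), abs=1e-12)

    def test_exact_branch_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(6, 2), (1, 5), (0, 7), (3, 3)]:
            a, bb, y = _decisions_with_discordance(b, c)
            res = mcnemar_test(a, bb, y)
            table = [[0, b], [c, 0]]
            sm = sm_mcnemar(table, exact=True)
            assert res.p_value == pytest.approx(float(sm.pvalue), abs=1e-9)
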