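import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from traumascore.validation import (
    SCORE_ORIENTATIONS,
    auc_concordance,
    auc_with_ci,
    cutoff_metrics,
    delong_paired_test,
    metrics_from_rates,
    pairwise_auc_table,
    roc_points,
    youden_optimal_cutoff,
)


def brute_force_auc(values, events):
    """All-pairs concordance count, ties one half."""
    values = np.asarray(values, float)
    x, y = values[np.asarray(events, bool)], values[~np.asarray(events, bool)]
    wins = (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
    return wins / (len(x) * len(y))


def exhaustive_youden(values, events, orientation):
    """Oracle: best J over every possible threshold placement."""
    values = np.asarray(values, float)
    events = np.asarray(events, bool)
    oriented = values if orientation == "higher" else -values
    candidates = np.concatenate([[oriented.min() - 1], np.unique(oriented)])
    best = -np.inf
    for c in candidates:
        pred = oriented > c
        sens = (pred & events).sum() / events.sum()
        spec = (~pred & ~events).sum() / (~events).sum()
        best = max(best, sens + spec - 1)
    return best


scores_and_labels = st.integers(8, 60).flatmap(
    lambda n: st.tuples(
        st.lists(
            st.integers(0, 12).map(float), min_size=n, max_size=n
        ),
        st.lists(st.booleans(), min_size=n, max_size=n),
    )
)


class TestROC:
    def test_perfect_separation_passes_top_left_corner(self):
        curve = roc_points([1, 2, 3, 4], [False, False, True, True], "higher")
        assert any(f == 0 and t == 1 for f, t in zip(curve.fpr, curve.tpr))
        assert (curve.fpr[0], curve.tpr[0]) == (0, 0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1, 1)

    def test_orientation_flip_rotates_curve(self):
        v = [1.0, 2.0, 2.0, 3.0, 5.0]
        e = [False, True, False, True, True]
        hi = roc_points(v, e, "higher")
        lo = roc_points(v, e, "lower")
        # 180-degree rotation about (1/2, 1/2)
        assert np.allclose(sorted(1 - hi.fpr), sorted(lo.fpr))
        assert np.allclose(sorted(1 - hi.tpr), sorted(lo.tpr))

    def test_tied_values_share_one_threshold(self):
        curve = roc_points([1, 2, 2, 3], [False, True, False, True], "higher")
        # thresholds: inf, 3, 2, 1 -> four points including both endpoints
        assert len(curve.thresholds) == 4
        assert auc_concordance([1, 2, 2, 3], [False, True, False, True], "higher") == 0.875

    def test_monotone_curve(self, rng):
        v = rng.normal(size=80)
        e = rng.random(80) < 0.3
        curve = roc_points(v, e, "higher")
        assert (np.diff(curve.tpr) >= 0).all() and (np.diff(curve.fpr) >= 0).all()

    @pytest.mark.parametrize(
        "events", [[True, True], [False, False]], ids=["all-event", "all-control"]
    )
    def test_degenerate_labels_raise(self, events):
        with pytest.raises(ValueError, match="degenerate"):
            roc_points([1.0, 2.0], events, "higher")


class TestAUC:
    def test_perfect_and_inverted_ranking(self):
        e = [False, False, True, True]
        assert auc_concordance([1, 2, 3, 4], e, "higher") == 1.0
        assert auc_concordance([4, 3, 2, 1], e, "higher") == 0.0

    @given(scores_and_labels)
    def test_equals_pair_counting_and_trapezoid_and_flip(self, data):
        values, events = data
        assume(any(events) and not all(events))
        auc = auc_concordance(values, events, "higher")
        assert auc == pytest.approx(brute_force_auc(values, events))
        assert auc == pytest.approx(
            roc_points(values, events, "higher").auc_trapezoid()
        )
        assert auc_concordance(values, events, "lower") == pytest.approx(1 - auc)

    def test_cross_check_against_sklearn(self, rng):
        for _ in range(20):
            v = rng.normal(size=100).round(1)  # rounding forces ties
            e = rng.random(100) < 0.35
            if not e.any() or e.all():
                continue
            assert auc_concordance(v, e, "higher") == pytest.approx(
                roc_auc_score(e, v)
            )

    def test_ci_contains_point_estimate_and_truncates(self, rng):
        v = rng.normal(size=60)
        e = rng.random(60) < 0.3
        res = auc_with_ci(v + e * 2.0, e, "higher")
        assert 0 <= res.ci_low <= res.auc <= res.ci_high <= 1

    def test_perfect_separation_gives_zero_se(self):
        res = auc_with_ci([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3, "higher")
        assert res.auc == 1.0 and res.se == 0.0

    def test_delong_se_close_to_bootstrap_se(self, rng):
        n = 40
        e = np.r_[np.zeros(28, bool), np.ones(12, bool)]
        v = rng.normal(size=n) + e * 1.2
        se = auc_with_ci(v, e, "higher").se
        boot = []
        for _ in range(2000):
            idx = np.r_[rng.integers(0, 28, 28), rng.integers(28, 40, 12)]
            boot.append(brute_force_auc(v[idx], e[idx]))
        assert se == pytest.approx(np.std(boot, ddof=1), rel=0.10)


class TestDeLongPaired:
    def test_identical_scores_give_p_one(self, rng):
        v = rng.normal(size=50)
        e = rng.random(50) < 0.4
        res = delong_paired_test(v, v, e, "higher", "higher")
        assert res.z == 0.0 and res.p == 1.0

    def test_antisymmetric_in_score_order(self, rng):
        a, b = rng.normal(size=60), rng.normal(size=60)
        e = rng.random(60) < 0.4
        ab = delong_paired_test(a, b, e, "higher", "higher")
        ba = delong_paired_test(b, a, e, "higher", "higher")
        assert ab.z == pytest.approx(-ba.z) and ab.p == pytest.approx(ba.p)

    def test_mixed_orientations_agree_with_negation(self, rng):
        a, b = rng.normal(size=60), rng.normal(size=60)
        e = rng.random(60) < 0.4
        direct = delong_paired_test(a, b, e, "higher", "higher")
        flipped = delong_paired_test(a, -b, e, "higher", "lower")
        assert flipped.z == pytest.approx(direct.z)

    def test_variance_of_single_auc_equals_paired_covariance_with_itself(self, rng):
        # cov(a, a) = var(a) => the difference a - a has zero variance
        v = rng.normal(size=40)
        e = rng.random(40) < 0.5
        res = delong_paired_test(v, v + 0.0, e, "higher", "higher")
        assert res.p == 1.0


class TestCutoffs:
    def test_perfect_split_attains_j_one(self):
        rep = youden_optimal_cutoff([1, 2, 3, 4], [False, False, True, True], "higher")
        assert rep.youden_j == 1.0 and 2 <= rep.cutoff < 3

    def test_constant_scores_give_j_zero(self):
        rep = youden_optimal_cutoff([5, 5, 5, 5], [False, True, False, True], "higher")
        assert rep.youden_j == 0.0

    @given(scores_and_labels)
    def test_j_matches_exhaustive_search(self, data):
        values, events = data
        assume(any(events) and not all(events))
        for orientation in ("higher", "lower"):
            rep = youden_optimal_cutoff(values, events, orientation)
            assert rep.youden_j == pytest.approx(
                exhaustive_youden(values, events, orientation)
            )

    def test_reported_metrics_reproduce_at_reported_cutoff(self, rng):
        v = rng.normal(size=120).round(1)
        e = rng.random(120) < 0.3
        rep = youden_optimal_cutoff(v, e, "higher")
        again = cutoff_metrics(v, e, rep.cutoff, "higher")
        assert again == rep

    def test_tie_break_prefers_specificity(self):
        # J = 0 everywhere; the all-negative cutoff (spec 1.0) must win
        rep = youden_optimal_cutoff([1, 2], [True, False], "higher")
        assert rep.specificity == 1.0

    def test_toy_contingency_table(self):
        # TP 3, FN 1, FP 2, TN 4 with a threshold at 5 (strict >)
        values = [6, 7, 8, 3, 9, 8, 2, 3, 4, 1]
        events = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        rep = cutoff_metrics(values, np.array(events, bool), 5, "higher")
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(0.7)

    def test_cutoff_below_all_values_predicts_everyone_positive(self):
        rep = cutoff_metrics([1, 2, 3], np.array([1, 0, 1], bool), 0, "higher")
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0
        assert np.isnan(rep.npv)


class TestRateIdentities:
    def test_perfect_test_for_any_prevalence(self):
        for prev in (0.01, 0.3, 0.9):
            assert metrics_from_rates(1, 1, prev) == (1.0, 1.0, 1.0)

    def test_identity_with_empirical_confusion_metrics(self, rng):
        v = rng.normal(size=200)
        e = rng.random(200) < 0.25
        rep = cutoff_metrics(v, e, 0.3, "higher")
        acc, ppv, npv = metrics_from_rates(
            rep.sensitivity, rep.specificity, e.mean()
        )
        assert acc == pytest.approx(rep.accuracy)
        assert ppv == pytest.approx(rep.ppv)
        assert npv == pytest.approx(rep.npv)

    def test_degenerate_denominator_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="PPV"):
            _, ppv, _ = metrics_from_rates(0.0, 1.0, 0.5)
        assert np.isnan(ppv)


class TestPairwiseTable:
    def test_symmetry_and_niss_orientation(self, rng):
        import pandas as pd

        n = 150
        sev = rng.normal(size=n)
        e = rng.random(n) < 1 / (1 + np.exp(-(sev - 1.2)))
        if not e.any() or e.all():
            pytest.skip("degenerate draw")
        panels = pd.DataFrame(
            {
                "niss": sev + rng.normal(scale=0.5, size=n),
                "rts": -(sev + rng.normal(scale=1.0, size=n)),
                "ps_mtos": -(sev + rng.normal(scale=0.8, size=n)),
                "ps_ntrd": -(sev + rng.normal(scale=0.7, size=n)),
            }
        )
        aucs, p_matrix, comparisons = pairwise_auc_table(panels, e)
        assert set(aucs) == set(SCORE_ORIENTATIONS)
        assert np.allclose(p_matrix.values, p_matrix.values.T, equal_nan=True)
        assert np.isnan(np.diag(p_matrix.values)).all()
        assert len(comparisons) == 6
        # all four scores track severity, so every AUC should beat chance
        assert all(res.auc > 0.5 for res in aucs.values())
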