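"""ROC/AUC, DeLong machinery, CV, threshold metrics: oracle comparisons."""

import numpy as np
import pytest

from perifuse import evaluation as ev


def brute_force_auc(labels, scores):
    """Pairwise Mann-Whitney count: the independent AUC oracle."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_and_all_ties(self):
        assert ev.roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]).auc == 1.0
        assert ev.roc_auc([1, 0, 1, 0], [0.5] * 4).auc == 0.5

    def test_small_case_equals_enumerated_pairs(self):
        # pairs: wins 3 of 4 -> 0.75
        curve = ev.roc_auc([1, 0, 1, 0], [0.8, 0.7, 0.3, 0.2])
        assert curve.auc == pytest.approx(0.75)
        assert curve.auc == pytest.approx(brute_force_auc([1, 0, 1, 0], [0.8, 0.7, 0.3, 0.2]))

    def test_curve_monotone_with_unit_endpoints(self):
        rng = np.random.default_rng(0)
        y = (rng.random(50) < 0.4).astype(int)
        s = rng.random(50) + 0.5 * y
        curve = ev.roc_auc(y, s)
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.thresholds) <= 0)

    def test_matches_brute_force_on_random_instances_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert ev.mann_whitney_auc(y, s) == pytest.approx(brute_force_auc(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            ev.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestAucCI:
    def test_interval_contains_point_and_degenerate_flagged(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 30 + [0] * 30)
        s = rng.random(60) + 0.4 * y
        lo, hi, degenerate = ev.auc_ci(y, s)
        auc = ev.mann_whitney_auc(y, s)
        assert lo <= auc <= hi and not degenerate
        lo2, hi2, deg2 = ev.auc_ci([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert deg2 and lo2 < 1.0 <= hi2  # widened by the continuity rule

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)

        def mean_width(n, reps=40):
            widths = []
            for _ in range(reps):
                y = np.array([1] * n + [0] * n)
                s = rng.standard_normal(2 * n) + 0.8 * y
                lo, hi, _ = ev.auc_ci(y, s)
                widths.append(hi - lo)
            return np.mean(widths)

        assert mean_width(160) < mean_width(40)

    def test_null_interval_symmetric_about_half(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 100 + [0] * 100)
        s = rng.standard_normal(200)
        lo, hi, _ = ev.auc_ci(y, s)
        mid = (lo + hi) / 2
        assert mid == pytest.approx(ev.mann_whitney_auc(y, s), abs=1e-9)


def jackknife_var_diff(y, sa, sb):
    """Leave-one-out variance oracle for the paired AUC difference."""
    n = len(y)
    diffs = []
    for i in range(n):
        keep = np.arange(n) != i
        yk = y[keep]
        if yk.min() == yk.max():
            continue
        diffs.append(brute_force_auc(yk, sa[keep]) - brute_force_auc(yk, sb[keep]))
    diffs = np.asarray(diffs)
    m = len(diffs)
    return (m - 1) / m * ((diffs - diffs.mean()) ** 2).sum()


class TestDelong:
    def test_identical_models_give_z0_p1(self):
        y = np.array([1, 0, 1, 0, 1, 0])
        s = np.array([0.9, 0.3, 0.7, 0.4, 0.6, 0.2])
        res = ev.delong_test(y, s, s)
        assert res.z == 0.0 and res.p_two_sided == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        y = np.array([1] * 40 + [0] * 40)
        sa = rng.standard_normal(80) + 0.9 * y
        sb = rng.standard_normal(80) + 0.3 * y
        ab = ev.delong_test(y, sa, sb)
        ba = ev.delong_test(y, sb, sa)
        assert ab.z == pytest.approx(-ba.z, rel=1e-12)
        assert ab.p_two_sided == pytest.approx(ba.p_two_sided, rel=1e-12)
        assert ab.p_two_sided == pytest.approx(
            2 * (1 - __import__("scipy.stats", fromlist=["norm"]).norm.cdf(abs(ab.z))),
            rel=1e-9,
        )

    def test_variance_agrees_with_jackknife_oracle(self):
        rng = np.random.default_rng(6)
        rel_errors = []
        for _ in range(5):
            y = np.array([1] * 30 + [0] * 30)
            sa = rng.standard_normal(60) + 0.8 * y
            sb = 0.5 * sa + rng.standard_normal(60) + 0.4 * y
            res = ev.delong_test(y, sa, sb)
            jk = jackknife_var_diff(y, sa, sb)
            rel_errors.append(abs(res.var_diff - jk) / jk)
        assert np.median(rel_errors) < 0.25

    def test_single_model_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(7)
        y = np.array([1] * 100 + [0] * 100)
        s = rng.standard_normal(200) + 1.0 * y
        _, var, _, _ = ev._auc_variance(y, s)
        boots = []
        for _ in range(1500):
            idx = rng.integers(0, 200, 200)
            if y[idx].min() == y[idx].max():
                continue
            boots.append(ev.mann_whitney_auc(y[idx], s[idx]))
        bvar = np.var(boots, ddof=1)
        assert abs(var - bvar) / bvar < 0.15

    def test_degenerate_zero_variance_flagged(self):
        y = np.array([1, 1, 0, 0])
        # one model perfectly right, the other perfectly wrong: every
        # placement value is constant, so the variance estimate collapses
        res = ev.delong_test(y, [0.9, 0.8, 0.2, 0.1], [0.1, 0.2, 0.8, 0.9])
        assert res.degenerate and res.p_two_sided == 0.0


class TestCrossValidate:
    @staticmethod
    def _plan(ids, labels, k=10):
        from perifuse.tabular import SplitPlan
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=0)
        folds = {}
        for f, (_, val) in enumerate(skf.split(np.zeros(len(ids)), labels)):
            for j in val:
                folds[ids[j]] = f
        return SplitPlan(train_ids=list(ids), test_ids=[], fold_assignments=folds, seed=0)

    @staticmethod
    def _linear_trainer(x, y):
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(max_iter=500).fit(x, y)
        return lambda xv: clf.predict_proba(xv)[:, 1]

    def test_ten_folds_and_perfect_signal(self):
        rng = np.random.default_rng(8)
        ids = [f"s{k}" for k in range(100)]
        y = np.array([1] * 50 + [0] * 50)
        x = y[:, None] + 0.01 * rng.standard_normal((100, 1))
        res = ev.cross_validate(x, y, self._plan(ids, y), self._linear_trainer)
        assert len(res.fold_aucs) == 10
        assert res.mean == pytest.approx(1.0)

    def test_label_permutation_gives_chance(self):
        rng = np.random.default_rng(9)
        ids = [f"s{k}" for k in range(200)]
        y = np.array([1] * 100 + [0] * 100)
        rng.shuffle(y)
        x = rng.standard_normal((200, 3))  # no relation to labels
        res = ev.cross_validate(x, y, self._plan(ids, y), self._linear_trainer)
        assert abs(res.mean - 0.5) < 0.1


class TestThresholdMetrics:
    def test_f1_from_published_precision_sensitivity_pairs(self):
        """Harmonic-mean consistency on precision/recall pairs reported for
        blood-disease and circulatory-disease chapter models."""
        assert round(ev.f1_score(0.85, 0.93), 2) == 0.89
        assert round(ev.f1_score(0.71, 0.77), 2) == 0.74

    def test_perfect_predictions(self):
        m = ev.threshold_metrics([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2])
        assert (
            m.accuracy == m.sensitivity == m.specificity == m.precision == m.f1 == 1.0
        )
        np.testing.assert_array_equal(m.confusion, np.eye(2))

    def test_counts_and_rates_identities(self):
        rng = np.random.default_rng(10)
        y = (rng.random(100) < 0.4).astype(int)
        s = rng.random(100)
        m = ev.threshold_metrics(y, s, threshold=0.5)
        c = m.counts
        assert m.sensitivity + c["fn"] / (c["tp"] + c["fn"]) == pytest.approx(1.0)
        assert m.specificity + c["fp"] / (c["tn"] + c["fp"]) == pytest.approx(1.0)
        np.testing.assert_allclose(m.confusion.sum(axis=1), 1.0)
        if m.precision is not None:
            assert m.f1 == pytest.approx(ev.f1_score(m.precision, m.sensitivity))

    def test_empty_predicted_positive_reported_as_undefined(self):
        m = ev.threshold_metrics([1, 0], [0.1, 0.2], threshold=0.9)
        assert m.precision is None and m.f1 is None


class TestEvaluateChapter:
    def test_refits_have_spread_and_identical_seeds_have_none(self):
        rng = np.random.default_rng(11)
        y = np.array([1] * 20 + [0] * 20)

        def fit_predict(seed):
            r = np.random.default_rng(seed)
            return r.random(40) + 0.8 * y

        rep = ev.evaluate_chapter("IX", fit_predict, y, n_refits=3)
        assert set(rep.metric_mean) == {"accuracy", "sensitivity", "specificity", "precision", "f1"}
        assert rep.metric_sd["accuracy"] >= 0
        same = ev.evaluate_chapter("IX", fit_predict, y, n_refits=3, seeds=[5, 5, 5])
        assert same.metric_sd["accuracy"] == 0.0 and same.test_auc_sd == 0.0
        # per-refit F1 identity
        for m in rep.refit_metrics:
            if m.precision is not None:
                assert m.f1 == pytest.approx(ev.f1_score(m.precision, m.sensitivity))

    def test_leakage_is_a_hard_error(self):
        y = np.array([1, 0, 1, 0])
        with pytest.raises(ValueError, match="leak|appear"):
            ev.evaluate_chapter(
                "III",
                lambda seed: np.random.default_rng(seed).random(4),
                y,
                n_refits=1,
                train_ids=["a", "b"],
                test_ids=["b", "c", "d", "e"],
            )
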