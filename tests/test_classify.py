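"""Feature selection, SVM, metrics, ROC and the nested LOOCV pipeline."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from connclass import (
    PipelineConfig,
    compute_metrics,
    roc_curve_points,
    run_loocv,
    select_features,
    train_svm,
)
from tests.conftest import cohort_from_features


class TestMetrics:
    def test_known_confusion_table(self):
        ss, sc, gr = compute_metrics(tp=19, tn=25, fp=1, fn=3)
        assert ss == pytest.approx(100 * 19 / 22)
        assert sc == pytest.approx(100 * 25 / 26)
        assert gr == pytest.approx(100 * 44 / 48)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        tp=st.integers(0, 30), fn=st.integers(0, 30),
        tn=st.integers(0, 30), fp=st.integers(0, 30),
    )
    def test_gr_is_prevalence_weighted_mean(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            with pytest.raises(ValueError):
                compute_metrics(tp, tn, fp, fn)
            return
        ss, sc, gr = compute_metrics(tp, tn, fp, fn)
        n_pat, n_con = tp + fn, tn + fp
        assert gr == pytest.approx((ss * n_pat + sc * n_con) / (n_pat + n_con))


class TestSelectFeatures:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        y = np.array([1, 1, 1, 0, 0, 0])
        sel, p = select_features(X, y, 2, p_ceiling=None)
        ref = np.array(
            [stats.ttest_ind(X[:3, j], X[3:, j]).pvalue for j in range(4)]
        )
        np.testing.assert_allclose(p, ref, rtol=1e-10)
        assert set(sel) == set(np.argsort(ref)[:2])

    def test_disjoint_support_column_ranked_first(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        y = np.array([1] * 5 + [0] * 5)
        X[:5, 2] += 100.0  # disjoint group supports on column 2
        sel, _ = select_features(X, y, 1, p_ceiling=None)
        assert sel.tolist() == [2]

    def test_all_columns_is_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 6))
        y = np.array([1] * 4 + [0] * 4)
        sel, _ = select_features(X, y, 6, p_ceiling=None)
        assert sel.tolist() == list(range(6))

    def test_single_class_rejected(self):
        X = np.random.default_rng(3).normal(size=(4, 3))
        with pytest.raises(ValueError, match="two classes"):
            select_features(X, np.ones(4), 2)

    def test_warns_above_p_ceiling(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        y = np.array([1, 1, 1, 0, 0, 0])
        with pytest.warns(UserWarning, match="ceiling"):
            select_features(X, y, 3, p_ceiling=1e-9)


def svm_dual_oracle(X, y_pm, gamma, C):
    """Exact dual solution by enumerating active-set patterns (small n).

    Each point is assigned alpha in {0, C, free}; the free alphas and bias
    solve the KKT equalities, and a pattern is accepted when all bound and
    box conditions hold.  The RBF Gram matrix is positive definite for
    distinct points, so the solution is unique.
    """
    n = len(y_pm)
    K = np.exp(-gamma * ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    tol = 1e-9
    for pattern in itertools.product((0, 1, 2), repeat=n):
        free = [i for i in range(n) if pattern[i] == 2]
        at_c = [i for i in range(n) if pattern[i] == 1]
        if not free:
            continue
        m = len(free)
        A = np.zeros((m + 1, m + 1))
        rhs = np.zeros(m + 1)
        for r, i in enumerate(free):
            A[r, :m] = y_pm[free] * K[i, free]
            A[r, m] = 1.0
            rhs[r] = y_pm[i] - C * np.sum(y_pm[at_c] * K[i, at_c])
        A[m, :m] = y_pm[free]
        rhs[m] = -C * np.sum(y_pm[at_c])
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            continue
        alpha = np.zeros(n)
        alpha[free] = sol[:m]
        alpha[at_c] = C
        b = sol[m]
        if np.any(alpha[free] <= tol) or np.any(alpha[free] >= C - tol):
            continue
        f = (alpha * y_pm) @ K + b
        margins = y_pm * f
        ok = all(margins[i] >= 1 - 1e-7 for i in range(n) if pattern[i] == 0)
        ok = ok and all(
            margins[i] <= 1 + 1e-7 for i in at_c
        )
        if ok:
            return alpha, b, f
    raise RuntimeError("no consistent active set found")


class TestSVM:
    def test_two_separated_points(self):
        Z = np.array([[0.0, 0.0], [3.0, 3.0]])
        y = np.array([0, 1])
        model = train_svm(Z, y, sigma=1.0)
        assert model.predict(Z).tolist() == [0, 1]

    def test_decision_values_match_dual_qp_oracle(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(8, 2))
        Z[:4] += 1.2
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        sigma, C = 1.5, 1.0
        gamma = 1.0 / (2 * sigma**2)
        model = train_svm(Z, y, sigma=sigma, C=C, tol=1e-10)
        _, _, f = svm_dual_oracle(Z, np.where(y == 1, 1.0, -1.0), gamma, C)
        np.testing.assert_allclose(model.decision_function(Z), f, atol=1e-6)

    def test_wide_kernel_limit_approaches_linear_svm(self):
        from sklearn.svm import SVC

        rng = np.random.default_rng(6)
        Z = rng.normal(size=(20, 2))
        Z -= Z.mean(axis=0)
        y = (Z[:, 0] + 0.3 * rng.normal(size=20) > 0).astype(int)
        sigma = 200.0
        rbf = train_svm(Z, y, sigma=sigma, C=0.5 * sigma**2)
        lin = SVC(kernel="linear", C=0.5).fit(Z, y)
        assert np.array_equal(rbf.predict(Z), lin.predict(Z))
        r = np.corrcoef(rbf.decision_function(Z), lin.decision_function(Z))[0, 1]
        assert r > 0.999

    def test_degenerate_identical_inputs_rejected(self):
        Z = np.ones((4, 2))
        with pytest.raises(ValueError, match="identical"):
            train_svm(Z, np.array([0, 1, 0, 1]), sigma=1.0)


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        *_, auc = roc_curve_points(scores, y)
        assert auc == pytest.approx(1.0)

    def test_random_scores_give_half(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=4000)
        y = rng.integers(0, 2, size=4000)
        *_, auc = roc_curve_points(scores, y)
        assert abs(auc - 0.5) < 0.05

    def test_matches_mann_whitney_pairwise_oracle(self):
        scores = np.array([0.3, -0.2, 0.9, 0.1, -0.5, 0.3])
        y = np.array([1, 0, 1, 1, 0, 0])
        *_, auc = roc_curve_points(scores, y)
        pos = scores[y == 1]
        neg = scores[y == 0]
        pairs = [
            1.0 if p > n else 0.5 if p == n else 0.0
            for p in pos for n in neg
        ]
        assert auc == pytest.approx(np.mean(pairs))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_points(np.array([0.1, 0.2]), np.array([1, 1]))


class TestLOOCV:
    def _signal_cohort(self, seed=8, n=12, n_regions=10, sep=4.0):
        rng = np.random.default_rng(seed)
        p = n_regions * (n_regions - 1) // 2
        X = rng.normal(size=(n, p))
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        X[y == 1, :5] += sep
        return cohort_from_features(X, y, n_regions), y

    def _config(self, **kw):
        # k large enough that the two-cluster neighbor graph stays connected
        base = dict(n_features=8, k_lle=6, d_lle=2, p_ceiling=None)
        base.update(kw)
        return PipelineConfig(**base)

    def test_separable_cohort_is_perfectly_classified(self):
        cohort, _ = self._signal_cohort(sep=8.0)
        result = run_loocv(cohort, self._config())
        assert result.generalization_rate == 100.0
        assert result.tp + result.fn == cohort.n_patients
        assert result.tn + result.fp == cohort.n_controls

    def test_no_leakage_from_left_out_subject(self):
        """Scrambling the held-out subject's features cannot change which
        features its fold selects."""
        cohort, y = self._signal_cohort()
        result = run_loocv(cohort, self._config())
        rng = np.random.default_rng(99)
        scrambled = [m.copy() for m in cohort.matrices]
        noise = rng.normal(size=scrambled[3].shape)
        noise = 0.5 * (noise + noise.T)
        np.fill_diagonal(noise, 0.0)
        scrambled[3] = noise
        X2 = np.vstack([m[np.triu_indices(10, 1)] for m in scrambled])
        cohort2 = cohort_from_features(X2, y, 10)
        result2 = run_loocv(cohort2, self._config())
        np.testing.assert_array_equal(
            result.folds[3].selected, result2.folds[3].selected
        )

    def test_deterministic_across_runs(self):
        cohort, _ = self._signal_cohort()
        a = run_loocv(cohort, self._config())
        b = run_loocv(cohort, self._config())
        assert a.to_json() == b.to_json()

    def test_no_lle_path(self):
        cohort, _ = self._signal_cohort(sep=8.0)
        result = run_loocv(cohort, self._config(use_lle=False))
        assert result.generalization_rate == 100.0

    def test_n_features_exceeding_length_rejected(self):
        cohort, _ = self._signal_cohort()
        with pytest.raises(ValueError, match="45"):
            run_loocv(cohort, self._config(n_features=100))

    def test_metric_identities_on_any_run(self, small_signal_cohort):
        cohort = small_signal_cohort.as_cohort()
        result = run_loocv(cohort, self._config(n_features=10, k_lle=6, d_lle=3))
        ss, sc, gr = compute_metrics(result.tp, result.tn, result.fp, result.fn)
        assert (result.sensitivity, result.specificity,
                result.generalization_rate) == (ss, sc, gr)
        assert 0.0 <= result.auc <= 1.0
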