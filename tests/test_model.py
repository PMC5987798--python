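import numpy as np
import pytest

from resectnet.features import CohortFeatures
from resectnet.model import (
    ClassWeightedLinearSVM,
    ElasticNetLogistic,
    TwoStepOutcomeClassifier,
    confusion_metrics,
    default_grid,
    elastic_net_objective,
    grid_search,
    loocv_evaluate,
    RegularisationGrid,
    select_features,
    uniform_prior_class_weights,
)


def _small_problem(rng, n=6, m=2):
    A = rng.normal(size=(n, m))
    y = np.array([1.0] * (n // 2) + [-1.0] * (n - n // 2))
    return A, y


class TestObjective:
    def test_zero_point_closed_form(self, rng):
        A, y = _small_problem(rng)
        assert elastic_net_objective(np.zeros(2), 0.0, A, y, 0.3, 0.7) == pytest.approx(6 * np.log(2))

    def test_penalty_free_limit_is_plain_loss(self, rng):
        A, y = _small_problem(rng)
        x = rng.normal(size=2)
        c = 0.4
        loss = sum(np.log1p(np.exp(-y[i] * (A[i] @ x + c))) for i in range(6))
        assert elastic_net_objective(x, c, A, y, 0.0, 0.0) == pytest.approx(loss, abs=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        A, y = _small_problem(rng, n=9, m=4)
        w = rng.uniform(0.5, 2.0, size=9)
        x = rng.normal(size=4)
        c = -0.3
        lam, rho = 0.17, 0.93
        expected = sum(w[i] * np.log(1 + np.exp(-y[i] * (x @ A[i] + c))) for i in range(9))
        expected += 0.5 * rho * sum(v * v for v in x) + lam * sum(abs(v) for v in x)
        assert elastic_net_objective(x, c, A, y, lam, rho, w) == pytest.approx(expected, abs=1e-12)


class TestElasticNetFit:
    def test_large_lambda_gives_exact_zero_weights(self, rng):
        A, y = _small_problem(rng)
        model = ElasticNetLogistic(lam=50.0, rho=0.1).fit(A, y)
        assert np.all(model.coef_ == 0.0)

    def test_null_model_intercept_is_weighted_log_odds(self):
        """With x = 0 the optimal intercept for a 36/17 class split is
        ln(36/17) ~ 0.7504."""
        rng = np.random.default_rng(7)
        A = rng.normal(size=(53, 3))
        y = np.array([1.0] * 36 + [-1.0] * 17)
        model = ElasticNetLogistic(lam=100.0, rho=0.0).fit(A, y)
        assert np.all(model.coef_ == 0.0)
        assert model.intercept_ == pytest.approx(np.log(36 / 17), abs=1e-6)

    def test_objective_beats_dense_grid_oracle(self, rng):
        """Convexity check: the fitted objective never exceeds the best
        value found by brute-force search over a fine (x1, x2, c) grid."""
        for trial in range(3):
            A, y = _small_problem(rng)
            lam, rho = 0.1, 0.5
            model = ElasticNetLogistic(lam=lam, rho=rho).fit(A, y)
            grid = np.linspace(-3, 3, 61)
            best = min(
                elastic_net_objective(np.array([x1, x2]), c, A, y, lam, rho)
                for x1 in grid for x2 in grid for c in np.linspace(-2, 2, 21)
            )
            assert model.objective_value_ <= best + 1e-6

    def test_objective_never_above_null_start(self, rng):
        A, y = _small_problem(rng, n=12, m=5)
        lam, rho = 0.2, 0.3
        model = ElasticNetLogistic(lam=lam, rho=rho).fit(A, y)
        null = elastic_net_objective(np.zeros(5), np.log(1.0), A, y, lam, rho)
        assert model.objective_value_ <= null + 1e-9

    def test_single_class_rejected(self, rng):
        A = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match="classes"):
            ElasticNetLogistic().fit(A, np.ones(4))

    def test_monotone_sparsity_in_lambda(self):
        rng = np.random.default_rng(42)
        A = rng.normal(size=(40, 30))
        beta = np.zeros(30)
        beta[:5] = 2.0
        y = np.where(A @ beta + 0.5 * rng.normal(size=40) > 0, 1.0, -1.0)
        counts = []
        for lam in default_grid().lam_values:
            model = ElasticNetLogistic(lam=float(lam), rho=0.51).fit(A, y)
            counts.append(int(model.selection_mask().sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSelection:
    def test_all_zero_gives_empty_mask(self, rng):
        A, y = _small_problem(rng)
        model = ElasticNetLogistic(lam=50.0, rho=0.1).fit(A, y)
        assert select_features(model).sum() == 0

    def test_mask_pattern_and_threshold(self):
        model = ElasticNetLogistic()
        model.coef_ = np.array([0.3, 0.0, -0.2, 1e-12])
        np.testing.assert_array_equal(model.selection_mask(), [1, 0, 1, 0])


class TestWeightedSVM:
    def test_uniform_prior_weights(self):
        y = np.array([1.0] * 36 + [-1.0] * 17)
        w = uniform_prior_class_weights(y)
        assert w[1.0] == pytest.approx(53 / 72)
        assert w[-1.0] == pytest.approx(53 / 34)

    def test_separable_balanced_toy_no_training_errors(self):
        X = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        clf = ClassWeightedLinearSVM().fit(X, y)
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_imbalance_shifts_boundary_toward_majority(self):
        """With overlapping classes at a 5:1 imbalance, uniform-prior
        weighting moves the decision boundary strictly closer to the
        majority mean than the unweighted SVM's boundary."""
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(-1.0, 1.2, 30), rng.normal(1.0, 1.2, 6)])[:, None]
        y = np.array([-1.0] * 30 + [1.0] * 6)
        weighted = ClassWeightedLinearSVM(C=1.0).fit(X, y)
        from sklearn.svm import SVC

        plain = SVC(kernel="linear", C=1.0).fit(X, y)
        b_weighted = -weighted.intercept_ / weighted.coef_[0]
        b_plain = -plain.intercept_[0] / plain.coef_[0, 0]
        majority_mean = X[:10].mean()
        assert abs(b_weighted - majority_mean) < abs(b_plain - majority_mean)

    def test_weighting_approximates_minority_duplication(self):
        """Duplicating every minority sample to reach balance gives (about)
        the same boundary as uniform-prior cost weighting."""
        rng = np.random.default_rng(9)
        Xmaj = rng.normal(-1.5, 0.8, size=(12, 2))
        Xmin = rng.normal(1.5, 0.8, size=(4, 2))
        X = np.vstack([Xmaj, Xmin])
        y = np.array([-1.0] * 12 + [1.0] * 4)
        weighted = ClassWeightedLinearSVM(C=1.0).fit(X, y)
        from sklearn.svm import SVC

        Xdup = np.vstack([Xmaj, np.repeat(Xmin, 3, axis=0)])
        ydup = np.array([-1.0] * 12 + [1.0] * 12)
        # duplication triples the minority count; the weighted SVM costs are
        # n/(2 n_k) = (16/24, 16/8): same 1:3 cost ratio up to overall C
        dup = SVC(kernel="linear", C=16 / 24).fit(Xdup, ydup)
        w1 = weighted.coef_ / np.linalg.norm(weighted.coef_)
        w2 = dup.coef_.ravel() / np.linalg.norm(dup.coef_)
        np.testing.assert_allclose(w1, w2, atol=1e-3)

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty feature"):
            ClassWeightedLinearSVM().fit(np.empty((4, 0)), np.array([1.0, 1, -1, -1]))


def _cohort(A, y):
    m = A.shape[1]
    return CohortFeatures(A=A, y=y, block_index=["connection_strength"] * m,
                          feature_names=[f"f{k}" for k in range(m)])


class TestLOOCV:
    def test_one_prediction_per_subject(self, rng):
        A = rng.normal(size=(10, 4))
        y = np.array([1.0] * 5 + [-1.0] * 5)
        ev = loocv_evaluate(_cohort(A, y), lam=0.1, rho=0.1)
        assert ev.n == 10
        assert len(ev.n_selected_per_fold) == 10

    def test_perfectly_separating_feature_gives_full_accuracy(self, rng):
        n = 12
        y = np.array([1.0] * 6 + [-1.0] * 6)
        A = rng.normal(size=(n, 5))
        A[:, 2] = y * 2.0 + rng.normal(0, 0.05, n)
        ev = loocv_evaluate(_cohort(A, y), lam=0.11, rho=0.11)
        assert ev.accuracy == 1.0

    def test_no_leakage_per_fold(self, rng):
        """Each LOOCV prediction must equal a two-step model fitted from
        scratch on the other subjects only."""
        A = rng.normal(size=(8, 6))
        y = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        feats = _cohort(A, y)
        ev = loocv_evaluate(feats, lam=0.05, rho=0.2)
        preds = []
        for i in range(8):
            tr = np.arange(8) != i
            clf = TwoStepOutcomeClassifier(lam=0.05, rho=0.2).fit(A[tr], y[tr])
            preds.append(float(clf.predict(A[i:i + 1])[0]))
        tp = sum(1 for p, t in zip(preds, y) if p == 1 and t == 1)
        tn = sum(1 for p, t in zip(preds, y) if p == -1 and t == -1)
        assert ev.accuracy == pytest.approx((tp + tn) / 8)

    def test_fallback_predicts_seizure_free(self, rng):
        A = rng.normal(size=(6, 3))
        y = np.array([1.0, 1, 1, 1, -1, -1])
        ev = loocv_evaluate(_cohort(A, y), lam=100.0, rho=0.1)
        # every fold falls back to the prior: all predicted +1
        assert ev.tp + ev.fp == 6
        assert len(ev.fallback_folds) == 6

    def test_unknown_scope_rejected(self, rng):
        A = rng.normal(size=(4, 2))
        y = np.array([1.0, 1, -1, -1])
        with pytest.raises(ValueError, match="selection_scope"):
            loocv_evaluate(_cohort(A, y), lam=0.1, rho=0.1, selection_scope="bogus")


class TestGridSearch:
    def test_default_grid_dimensions(self):
        g = default_grid()
        assert len(g.lam_values) == 20 and len(g.rho_values) == 40
        assert g.n_points == 800
        assert g.lam_values[0] == pytest.approx(0.01) and g.lam_values[-1] == pytest.approx(0.96)
        assert g.rho_values[0] == pytest.approx(0.01) and g.rho_values[-1] == pytest.approx(1.96)

    def test_single_point_grid_returns_it(self, rng):
        A = rng.normal(size=(8, 3))
        y = np.array([1.0] * 4 + [-1.0] * 4)
        g = RegularisationGrid(lam_values=[0.21], rho_values=[0.41])
        res = grid_search(_cohort(A, y), grid=g)
        assert (res.best_lam, res.best_rho) == (0.21, 0.41)

    def test_tie_break_prefers_fewer_features_then_larger_lambda(self, rng):
        """On a toy where one strong feature separates the classes, large
        lambda keeps accuracy while shrinking the selection, so the search
        must settle on the sparser, larger-lambda point."""
        n = 14
        y = np.array([1.0] * 7 + [-1.0] * 7)
        A = rng.normal(size=(n, 8)) * 0.3
        A[:, 0] = y * 3.0
        g = RegularisationGrid(lam_values=[0.01, 0.46], rho_values=[0.51])
        res = grid_search(_cohort(A, y), grid=g)
        assert res.best_evaluation.accuracy == 1.0
        assert res.best_lam == 0.46


class TestConfusionMetrics:
    def test_reported_confusion_table_arithmetic(self):
        ev = confusion_metrics(tp=31, fp=6, fn=5, tn=11)
        assert ev.accuracy == pytest.approx(0.792, abs=5e-4)
        assert ev.sensitivity == pytest.approx(0.861, abs=5e-4)
        assert ev.specificity == pytest.approx(0.647, abs=5e-4)
        assert ev.false_positive_rate == pytest.approx(0.353, abs=5e-4)
        assert ev.false_negative_rate == pytest.approx(0.139, abs=5e-4)

    def test_perfect_prediction(self):
        ev = confusion_metrics(tp=10, fp=0, fn=0, tn=5)
        assert ev.accuracy == 1.0 and ev.false_positive_rate == 0.0 and ev.false_negative_rate == 0.0

    def test_all_predicted_positive_with_imbalanced_cohort(self):
        ev = confusion_metrics(tp=36, fp=17, fn=0, tn=0)
        assert ev.accuracy == pytest.approx(36 / 53)
        assert ev.specificity == 0.0

    def test_empty_actual_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics(tp=5, fp=0, fn=1, tn=0)
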