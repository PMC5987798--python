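"""Two-step outcome classification: elastic-net logistic feature selection
followed by a class-weighted linear SVM, evaluated by leave-one-out
cross-validation over an (l1, l2) regularisation grid.

The selection step minimises the weighted elastic-net logistic objective

    F(x, c) = sum_i w_i log(1 + exp(-y_i (x.a_i + c)))
              + (rho/2) ||x||_2^2 + lambda ||x||_1

with an unpenalised intercept c, by accelerated proximal gradient (FISTA)
with backtracking; the l1 proximal step is exact soft-thresholding, so
unselected coefficients are exactly zero.  Features with |x_j| above a small
threshold form a binary mask; the masked feature space feeds a soft-margin
linear SVM whose per-class misclassification cost is n / (2 n_k) (uniform
class priors), countering the seizure-free / not-seizure-free imbalance.

Estimators follow scikit-learn conventions (get_params/set_params, fitted
attributes with trailing underscores) and compose with sklearn tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "elastic_net_objective",
    "ElasticNetLogistic",
    "select_features",
    "uniform_prior_class_weights",
    "ClassWeightedLinearSVM",
    "TwoStepOutcomeClassifier",
    "ClassifierEvaluation",
    "confusion_metrics",
    "loocv_evaluate",
    "RegularisationGrid",
    "default_grid",
    "GridSearchResult",
    "grid_search",
]

ZERO_WEIGHT_THRESHOLD = 1e-8


# ---------------------------------------------------------------------------
# elastic-net logistic regression


def elastic_net_objective(x, c, A, y, lam, rho, sample_weight=None) -> float:
    """Weighted elastic-net logistic objective, overflow-safe."""
    A = np.asarray(A, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    margins = y * (A @ x + c)
    loss = float(np.sum(w * np.logaddexp(0.0, -margins)))
    return loss + 0.5 * rho * float(x @ x) + lam * float(np.abs(x).sum())


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


class ElasticNetLogistic(BaseEstimator, ClassifierMixin):
    """l1+l2-regularised logistic regression solved by FISTA.

    Parameters
    ----------
    lam : float
        l1 penalty weight (sparsity).
    rho : float
        l2 penalty weight (smoothness); the quadratic term is (rho/2)||x||^2.
    tol : float
        Relative objective-change convergence tolerance.
    max_iter : int
        Iteration cap; non-convergence sets ``converged_ = False`` rather
        than raising.

    Labels must be +1 / -1.  The intercept is unpenalised.
    """

    def __init__(self, lam: float = 0.1, rho: float = 0.1, tol: float = 1e-8, max_iter: int = 100_000):
        self.lam = lam
        self.rho = rho
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, sample_weight=None):
        X, y = check_X_y(X, y, ensure_min_features=0)
        y = np.asarray(y, dtype=float)
        if not set(np.unique(y)) <= {-1.0, 1.0}:
            raise ValueError("labels must be +1 / -1")
        if len(set(y)) < 2:
            raise ValueError("both classes must be present")
        if self.lam < 0 or self.rho < 0:
            raise ValueError("penalties must be non-negative")
        n, m = X.shape
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)

        # parameters packed as z = [x (m), c]; only x is soft-thresholded
        def smooth(z):
            x, c = z[:m], z[m]
            margins = y * (X @ x + c)
            return float(np.sum(w * np.logaddexp(0.0, -margins))) + 0.5 * self.rho * float(x @ x)

        def grad(z):
            x, c = z[:m], z[m]
            margins = y * (X @ x + c)
            # d/dm log(1+e^{-m}) = -sigma(-m)
            s = w * expit(-margins)
            gx = -(X.T @ (s * y)) + self.rho * x
            gc = -float(np.sum(s * y))
            return np.concatenate([gx, [gc]])

        def prox(z, step):
            out = z.copy()
            out[:m] = _soft_threshold(z[:m], step * self.lam)
            return out

        def objective(z):
            return smooth(z) + self.lam * float(np.abs(z[:m]).sum())

        # start at x = 0 with the weighted log-odds intercept
        wp = float(w[y > 0].sum())
        wn = float(w[y < 0].sum())
        z = np.zeros(m + 1)
        z[m] = np.log(wp / wn)

        L = max(1.0, 0.25 * (np.sum(w) + float(np.einsum("ij,ij->", X, X)) / max(n, 1)))
        zk = z.copy()
        tk = 1.0
        fz = objective(z)
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            g = grad(zk)
            gk = smooth(zk)
            while True:
                znew = prox(zk - g / L, 1.0 / L)
                d = znew - zk
                if smooth(znew) <= gk + float(g @ d) + 0.5 * L * float(d @ d) + 1e-12:
                    break
                L *= 2.0
            tnew = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
            zk = znew + ((tk - 1.0) / tnew) * (znew - z)
            fnew = objective(znew)
            # monotone restart: FISTA momentum can overshoot
            if fnew > fz:
                zk = znew
                tnew = 1.0
            rel = abs(fz - fnew) / max(1.0, abs(fz))
            z, tk, fz = znew, tnew, fnew
            if rel < self.tol:
                converged = True
                break
            L *= 0.95  # allow the step to grow back

        self.coef_ = z[:m]
        self.intercept_ = float(z[m])
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.objective_value_ = objective(z)
        self.classes_ = np.array([-1.0, 1.0])
        self.n_features_in_ = m
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d >= 0, 1.0, -1.0)

    def selection_mask(self, threshold: float = ZERO_WEIGHT_THRESHOLD) -> np.ndarray:
        """Binary mask of features with non-zero weight."""
        check_is_fitted(self, "coef_")
        return (np.abs(self.coef_) > threshold).astype(int)


def select_features(model: ElasticNetLogistic, threshold: float = ZERO_WEIGHT_THRESHOLD) -> np.ndarray:
    """Binary selection mask from a fitted elastic-net model."""
    return model.selection_mask(threshold)


# ---------------------------------------------------------------------------
# class-weighted linear SVM


def uniform_prior_class_weights(y) -> dict:
    """Per-class misclassification cost n / (K n_k): uniform class priors."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n, K = len(y), len(classes)
    return {cls: n / (K * cnt) for cls, cnt in zip(classes.tolist(), counts.tolist())}


class ClassWeightedLinearSVM(BaseEstimator, ClassifierMixin):
    """Soft-margin linear SVM with uniform-prior class reweighting.

    The per-class cost n/(2 n_k) stops the classifier from learning the
    empirical 68:32 outcome imbalance instead of the features.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_features=0)
        if X.shape[1] == 0:
            raise ValueError("empty feature set; caller must fall back to the prior")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        self.class_weight_ = uniform_prior_class_weights(y)
        self.svc_ = SVC(kernel="linear", C=self.C, class_weight=self.class_weight_)
        self.svc_.fit(X, y)
        self.coef_ = self.svc_.coef_.ravel()
        self.intercept_ = float(self.svc_.intercept_[0])
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(X)

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(X)


# ---------------------------------------------------------------------------
# the two-step classifier


class TwoStepOutcomeClassifier(BaseEstimator, ClassifierMixin):
    """Elastic-net feature selection followed by a class-weighted linear SVM.

    If the elastic net selects no feature (lam at or above the critical
    value), the classifier falls back to a constant prediction.  With
    uniform class priors the two classes tie, so the tie is broken toward
    the +1 (seizure-free) class; ``fallback_`` records that this happened.
    """

    def __init__(
        self,
        lam: float = 0.1,
        rho: float = 0.1,
        svm_C: float = 1.0,
        zero_threshold: float = ZERO_WEIGHT_THRESHOLD,
        tol: float = 1e-8,
        max_iter: int = 100_000,
    ):
        self.lam = lam
        self.rho = rho
        self.svm_C = svm_C
        self.zero_threshold = zero_threshold
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, sample_weight=None):
        X, y = check_X_y(X, y, ensure_min_features=0)
        self.enet_ = ElasticNetLogistic(lam=self.lam, rho=self.rho, tol=self.tol, max_iter=self.max_iter)
        self.enet_.fit(X, y, sample_weight=sample_weight)
        self.selection_mask_ = self.enet_.selection_mask(self.zero_threshold)
        self.n_selected_ = int(self.selection_mask_.sum())
        self.classes_ = np.array([-1.0, 1.0])
        self.n_features_in_ = X.shape[1]
        if self.n_selected_ == 0:
            self.fallback_ = True
            self.svm_ = None
        else:
            self.fallback_ = False
            self.svm_ = ClassWeightedLinearSVM(C=self.svm_C)
            self.svm_.fit(X[:, self.selection_mask_.astype(bool)], y)
        return self

    def predict(self, X):
        check_is_fitted(self, "selection_mask_")
        X = np.asarray(X, dtype=float)
        if self.fallback_:
            return np.ones(X.shape[0])
        return np.asarray(self.svm_.predict(X[:, self.selection_mask_.astype(bool)]), dtype=float)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ClassifierEvaluation:
    """Confusion counts and derived rates; positive class = seizure free."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    false_positive_rate: float
    false_negative_rate: float
    n_selected_per_fold: list[int] = field(default_factory=list)
    fallback_folds: list[int] = field(default_factory=list)
    single_class_folds: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def mean_selected(self) -> float:
        return float(np.mean(self.n_selected_per_fold)) if self.n_selected_per_fold else 0.0


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> ClassifierEvaluation:
    """Derive accuracy, sensitivity, specificity, fall-out and miss rate."""
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise ValueError("negative confusion count")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion table")
    pos = tp + fn
    neg = tn + fp
    if pos == 0 or neg == 0:
        raise ValueError("an actual class is empty; rates undefined")
    sens = tp / pos
    spec = tn / neg
    return ClassifierEvaluation(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        false_positive_rate=1.0 - spec,
        false_negative_rate=1.0 - sens,
    )


def loocv_evaluate(
    features,
    lam: float,
    rho: float,
    selection_scope: str = "per_fold",
    svm_C: float = 1.0,
) -> ClassifierEvaluation:
    """Leave-one-out cross-validation of the two-step classifier.

    ``features`` is a CohortFeatures (or any object with A, y,
    sample_weights).  ``selection_scope``:

    - "per_fold": the elastic net is refitted inside every training fold
      (no leakage; the default);
    - "full_cohort": the mask is computed once on all subjects and reused,
      so the held-out subject influences its own feature selection.
    """
    A = np.asarray(features.A, dtype=float)
    y = np.asarray(features.y, dtype=float)
    w = getattr(features, "sample_weights", None)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("LOOCV requires at least 2 subjects")
    if selection_scope not in ("per_fold", "full_cohort"):
        raise ValueError(f"unknown selection_scope {selection_scope!r}")

    full_mask = None
    if selection_scope == "full_cohort":
        enet = ElasticNetLogistic(lam=lam, rho=rho).fit(A, y, sample_weight=w)
        full_mask = enet.selection_mask().astype(bool)

    preds = np.zeros(n)
    n_sel: list[int] = []
    fallback_folds: list[int] = []
    single_class_folds: list[int] = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        if len(set(ytr)) < 2:
            single_class_folds.append(i)
            # degenerate training fold: predict the (uniform) prior
            preds[i] = 1.0
            n_sel.append(0)
            continue
        if selection_scope == "full_cohort":
            cols = full_mask
            n_sel.append(int(cols.sum()))
            if cols.sum() == 0:
                fallback_folds.append(i)
                preds[i] = 1.0
                continue
            svm = ClassWeightedLinearSVM(C=svm_C).fit(A[np.ix_(tr, cols)], ytr)
            preds[i] = float(svm.predict(A[i:i + 1, cols])[0])
        else:
            clf = TwoStepOutcomeClassifier(lam=lam, rho=rho, svm_C=svm_C)
            clf.fit(A[tr], ytr, sample_weight=w[tr])
            n_sel.append(clf.n_selected_)
            if clf.fallback_:
                fallback_folds.append(i)
            preds[i] = float(clf.predict(A[i:i + 1])[0])

    tp = int(np.sum((preds == 1) & (y == 1)))
    fp = int(np.sum((preds == 1) & (y == -1)))
    fn = int(np.sum((preds == -1) & (y == 1)))
    tn = int(np.sum((preds == -1) & (y == -1)))
    ev = confusion_metrics(tp, fp, fn, tn)
    ev.n_selected_per_fold = n_sel
    ev.fallback_folds = fallback_folds
    ev.single_class_folds = single_class_folds
    return ev


# ---------------------------------------------------------------------------
# grid search


@dataclass
class RegularisationGrid:
    """Arithmetic (lam, rho) ladders for the grid search."""

    lam_values: np.ndarray
    rho_values: np.ndarray

    def __post_init__(self) -> None:
        self.lam_values = np.asarray(self.lam_values, dtype=float)
        self.rho_values = np.asarray(self.rho_values, dtype=float)
        if self.lam_values.size == 0 or self.rho_values.size == 0:
            raise ValueError("empty grid")

    @property
    def n_points(self) -> int:
        return self.lam_values.size * self.rho_values.size


def default_grid() -> RegularisationGrid:
    """lam 0.01..0.96 (20 values) and rho 0.01..1.96 (40 values), step 0.05."""
    return RegularisationGrid(
        lam_values=0.01 + 0.05 * np.arange(20),
        rho_values=0.01 + 0.05 * np.arange(40),
    )


@dataclass
class GridSearchResult:
    best_lam: float
    best_rho: float
    best_evaluation: ClassifierEvaluation
    results: dict  # (lam, rho) -> ClassifierEvaluation


def grid_search(
    features,
    grid: RegularisationGrid | None = None,
    selection_scope: str = "per_fold",
    svm_C: float = 1.0,
) -> GridSearchResult:
    """LOOCV grid search over (lam, rho).

    Maximises accuracy; ties are broken toward fewer mean selected features
    and then toward larger lam — the smallest feature set that separates
    the outcome classes most accurately.
    """
    grid = grid or default_grid()
    results: dict[tuple[float, float], ClassifierEvaluation] = {}
    best_key = None
    best = None
    for lam in grid.lam_values:
        for rho in grid.rho_values:
            ev = loocv_evaluate(features, lam=float(lam), rho=float(rho),
                                selection_scope=selection_scope, svm_C=svm_C)
            results[(float(lam), float(rho))] = ev
            key = (ev.accuracy, -ev.mean_selected, float(lam))
            if best is None or key > best:
                best = key
                best_key = (float(lam), float(rho))
    return GridSearchResult(
        best_lam=best_key[0], best_rho=best_key[1],
        best_evaluation=results[best_key], results=results,
    )
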