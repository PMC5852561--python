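"""Linear SVMs: the sparse 1-norm squared-hinge machine and its 2-norm
counterpart used for evaluation.

The 1-norm SVM minimizes, over weights ``w`` and unpenalized intercept ``b``,

    C * sum_i max(0, 1 - y_i (w^T x_i + b))**2  +  (1 - C) * ||w||_1

with the tradeoff ``C`` restricted to the open interval (0, 1): it is the
convex-combination weight between the squared-hinge loss and the lasso
penalty (a conventional penalty parameter would be lambda = (1-C)/C).
Because the penalty is the 1-norm, the optimal weight vector is sparse and
the surviving nonzero-weight features form a signature.

The solver splits ``w = w_plus - w_minus`` with ``w_plus, w_minus >= 0``,
which turns the objective into a smooth, bound-constrained convex program
solved with L-BFGS-B, followed by one exact coordinate-descent polish pass
over the active coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_array, check_is_fitted


def l1svm_objective(X, y, w, b, C) -> float:
    """Evaluate the 1-norm squared-hinge objective at (w, b)."""
    margins = 1.0 - y * (X @ w + b)
    hinge = np.maximum(margins, 0.0)
    return C * float(hinge @ hinge) + (1.0 - C) * float(np.abs(w).sum())


def _validate_binary(X, y, C):
    X = check_array(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if not (0.0 < C < 1.0):
        raise ValueError(f"C must lie strictly in (0, 1), got {C}")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    signed = np.where(y == classes[1], 1.0, -1.0)
    return X, signed, classes


def _coordinate_polish(X, ys, w, b, C, sweeps: int = 40, tol: float = 1e-14):
    """Exact cyclic coordinate descent on the split objective.

    Each coordinate subproblem (one weight, or the intercept) is a
    piecewise quadratic with a closed-form soft-threshold minimizer; a few
    sweeps sharpen the L-BFGS-B solution to high precision and snap
    near-zero weights to exact zeros.
    """
    n, p = X.shape
    f = X @ w + b  # cached decision values
    lam = 1.0 - C
    for _ in range(sweeps):
        # KKT screening: a zero coordinate can only leave zero when its
        # smooth-part gradient exceeds the penalty slope, so restrict the
        # sweep to active or violating coordinates
        hinge = np.maximum(1.0 - ys * f, 0.0)
        grad = -2.0 * C * (X.T @ (hinge * ys))
        candidates = np.flatnonzero((w != 0.0) | (np.abs(grad) > lam * (1.0 + 1e-12)))
        delta = 0.0
        for j in candidates:
            xj = X[:, j]
            f_minus = f - xj * w[j]
            margins = 1.0 - ys * f_minus
            # active-set Newton on the 1-D convex function: iterate the
            # closed-form solution for a frozen active set until stable
            wj = w[j]
            for _ in range(50):
                active = (margins - ys * xj * wj) > 0
                a = 2.0 * C * float((xj[active] ** 2).sum())
                if a <= 0:
                    wj_new = 0.0
                else:
                    g = 2.0 * C * float((ys[active] * xj[active] * margins[active]).sum())
                    # minimize a/2 (v - g/a)^2 + lam |v|
                    target = g / a
                    wj_new = np.sign(target) * max(abs(target) - lam / a, 0.0)
                if abs(wj_new - wj) <= 1e-16 * max(1.0, abs(wj)):
                    wj = wj_new
                    break
                wj = wj_new
            if wj != w[j]:
                delta = max(delta, abs(wj - w[j]))
                f = f_minus + xj * wj
                w[j] = wj
        # intercept: unpenalized 1-D squared hinge
        f_minus = f - b
        margins = 1.0 - ys * f_minus
        bj = b
        for _ in range(50):
            active = (margins - ys * bj) > 0
            cnt = int(active.sum())
            if cnt == 0:
                break
            b_new = float((ys[active] * margins[active]).sum()) / cnt
            if abs(b_new - bj) <= 1e-16 * max(1.0, abs(bj)):
                bj = b_new
                break
            bj = b_new
        if bj != b:
            delta = max(delta, abs(bj - b))
            f = f_minus + bj
            b = bj
        if delta < tol:
            break
    return w, b


class L1NormSVC(BaseEstimator, ClassifierMixin):
    """Binary linear SVM with squared-hinge loss and 1-norm penalty.

    Parameters
    ----------
    C : float in (0, 1)
        Convex tradeoff between loss (weight ``C``) and the lasso penalty
        (weight ``1 - C``).  Small ``C`` forces ``w`` toward zero; ``C``
        near 1 fits the training data as closely as possible.
    tol : float
        Gradient tolerance passed to L-BFGS-B.
    max_iter : int
        Iteration cap for L-BFGS-B.
    polish : bool
        Run the exact coordinate-descent polish after L-BFGS-B.

    Attributes
    ----------
    coef_ : ndarray of shape (1, n_features)
    intercept_ : ndarray of shape (1,)
    classes_ : ndarray of shape (2,)
        Sorted labels; ``classes_[1]`` is the positive class.
    objective_value_ : float
        Objective evaluated at the returned solution.
    """

    def __init__(self, C: float = 0.5, tol: float = 1e-10, max_iter: int = 5000, polish: bool = True):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.polish = polish

    def fit(self, X, y, coef_init=None, intercept_init=None):
        X, ys, classes = _validate_binary(X, y, self.C)
        n, p = X.shape
        C = float(self.C)

        def fun_grad(v):
            wp, wn, b = v[:p], v[p : 2 * p], v[2 * p]
            w = wp - wn
            margins = 1.0 - ys * (X @ w + b)
            hinge = np.maximum(margins, 0.0)
            val = C * hinge @ hinge + (1.0 - C) * (wp.sum() + wn.sum())
            gw = -2.0 * C * (X.T @ (hinge * ys))
            gb = -2.0 * C * float(hinge @ ys)
            grad = np.concatenate([gw + (1.0 - C), -gw + (1.0 - C), [gb]])
            return val, grad

        x0 = np.zeros(2 * p + 1)
        if coef_init is not None:
            w0 = np.asarray(coef_init, dtype=float).ravel()
            x0[:p] = np.maximum(w0, 0.0)
            x0[p : 2 * p] = np.maximum(-w0, 0.0)
        if intercept_init is not None:
            x0[2 * p] = float(np.ravel(intercept_init)[0])

        bounds = [(0.0, None)] * (2 * p) + [(None, None)]
        res = minimize(
            fun_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": 1e-15, "gtol": self.tol, "maxfun": 10 * self.max_iter},
        )
        w = res.x[:p] - res.x[p : 2 * p]
        b = float(res.x[2 * p])
        if self.polish:
            w, b = _coordinate_polish(X, ys, w.copy(), b, C)

        self.classes_ = classes
        self.coef_ = w.reshape(1, -1)
        self.intercept_ = np.array([b])
        self.objective_value_ = l1svm_objective(X, ys, w, b, C)
        self.n_iter_ = int(res.nit)
        self.n_features_in_ = p
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_.ravel() + self.intercept_[0]

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= 0, self.classes_[1], self.classes_[0])


def fit_l1svm(X, y, C, **kwargs) -> L1NormSVC:
    """Functional wrapper: fit a binary 1-norm SVM on samples x features X."""
    return L1NormSVC(C=C, **kwargs).fit(X, y)


def nonzero_genes(model, eps_w: float = 1e-6, feature_names=None) -> dict:
    """Features with weight magnitude above the relative tolerance.

    A weight counts as nonzero when ``|w_k| > eps_w * max(1, ||w||_inf)``;
    with ``eps_w = 0`` this degenerates to bit-exact nonzeroness.  Returns
    feature -> |weight|.
    """
    w = np.asarray(model.coef_).ravel()
    if feature_names is None:
        feature_names = np.arange(w.size)
    cutoff = eps_w * max(1.0, float(np.abs(w).max(initial=0.0)))
    return {
        feature_names[k]: float(abs(w[k]))
        for k in range(w.size)
        if abs(w[k]) > cutoff
    }


class OneVsRestL1SVM(BaseEstimator, ClassifierMixin):
    """One-vs-rest multiclass wrapper around :class:`L1NormSVC`.

    One sparse binary machine is fitted per class (that class positive,
    the rest negative); prediction takes the argmax of the per-class
    decision values, with ties broken toward the earliest class in sorted
    label order (Basal < Her2 < LumA < LumB for the intrinsic subtypes).
    Each submodel's nonzero weights attribute genes to subtypes.
    """

    def __init__(self, C: float = 0.5, tol: float = 1e-10, max_iter: int = 5000, polish: bool = True):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.polish = polish

    def fit(self, X, y, coef_init=None):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes for one-vs-rest")
        for c in self.classes_:
            if (y == c).sum() < 2:
                raise ValueError(f"class {c!r} has fewer than 2 samples")
        self.estimators_ = []
        for k, c in enumerate(self.classes_):
            ys = np.where(y == c, 1, -1)
            est = L1NormSVC(C=self.C, tol=self.tol, max_iter=self.max_iter, polish=self.polish)
            init = None if coef_init is None else coef_init[k]
            est.fit(X, ys, coef_init=init)
            self.estimators_.append(est)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        return np.column_stack([est.decision_function(X) for est in self.estimators_])

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def coef_matrix(self) -> np.ndarray:
        """Per-class weight rows, shape (n_classes, n_features)."""
        check_is_fitted(self, "estimators_")
        return np.vstack([est.coef_ for est in self.estimators_])

    def nonzero_by_class(self, eps_w: float = 1e-6, feature_names=None) -> dict:
        """class label -> {feature: |weight|} over that class's submodel."""
        return {
            c: nonzero_genes(est, eps_w=eps_w, feature_names=feature_names)
            for c, est in zip(self.classes_, self.estimators_)
        }

    def nonzero_union(self, eps_w: float = 1e-6, feature_names=None) -> set:
        union: set = set()
        for genes in self.nonzero_by_class(eps_w=eps_w, feature_names=feature_names).values():
            union |= set(genes)
        return union


def fit_ovr(X, y, C, **kwargs) -> OneVsRestL1SVM:
    """Functional wrapper: one-vs-rest 1-norm SVM on samples x features X."""
    return OneVsRestL1SVM(C=C, **kwargs).fit(X, y)


class L2NormSVC(BaseEstimator, ClassifierMixin):
    """Standard linear 2-norm SVM (squared hinge), one-vs-rest multiclass.

    Thin deterministic wrapper over liblinear used as the downstream
    classifier when scoring a selected signature; ``C2`` is the usual
    loss/penalty tradeoff of that formulation (not the convex-combination
    ``C`` of the 1-norm machine).
    """

    def __init__(self, C2: float = 1.0):
        self.C2 = C2

    def fit(self, X, y):
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes")
        self._svc = LinearSVC(C=self.C2, penalty="l2", loss="squared_hinge", dual=False)
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        self.n_features_in_ = self._svc.n_features_in_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "_svc")
        return self._svc.decision_function(X)

    def predict(self, X):
        check_is_fitted(self, "_svc")
        return self._svc.predict(X)


def fit_l2svm(X, y, C2: float = 1.0) -> L2NormSVC:
    return L2NormSVC(C2=C2).fit(X, y)
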