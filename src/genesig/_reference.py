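"""Slow reference solver for the 1-norm squared-hinge SVM objective.

Accelerated proximal gradient (FISTA with adaptive restart) on

    C * sum_i max(0, 1 - y_i (w^T x_i + b))**2 + (1 - C) * ||w||_1

run from a cold start with an exact Lipschitz step.  This implementation is
deliberately independent of the production L-BFGS-B solver in
:mod:`genesig.svm` and exists for verification on small instances; it is
not meant to be fast.
"""

from __future__ import annotations

import numpy as np

from .svm import l1svm_objective


def solve_l1svm_reference(X, y, C, max_iter: int = 200_000, tol: float = 1e-14):
    """Return (w, b, objective) minimizing the 1-norm SVM objective.

    ``y`` must already be signed (+1/-1).
    """
    X = np.asarray(X, dtype=float)
    ys = np.asarray(y, dtype=float)
    n, p = X.shape
    C = float(C)
    lam = 1.0 - C

    # smooth part f(w, b) = C * sum h^2 with h = max(0, 1 - ys*(Xw + b));
    # grad Lipschitz constant 2C * ||[X, 1]||_2^2 (intercept as extra column)
    A = np.column_stack([X, np.ones(n)])
    L = 2.0 * C * np.linalg.norm(A, 2) ** 2
    step = 1.0 / L

    w = np.zeros(p)
    b = 0.0
    zw, zb = w.copy(), b  # extrapolated point
    t = 1.0
    prev_obj = l1svm_objective(X, ys, w, b, C)
    stall = 0
    for _ in range(max_iter):
        margins = 1.0 - ys * (X @ zw + zb)
        hinge = np.maximum(margins, 0.0)
        gw = -2.0 * C * (X.T @ (hinge * ys))
        gb = -2.0 * C * float(hinge @ ys)
        w_new = zw - step * gw
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * lam, 0.0)
        b_new = zb - step * gb

        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        beta = (t - 1.0) / t_new
        # adaptive restart on objective increase
        obj = l1svm_objective(X, ys, w_new, b_new, C)
        if obj > prev_obj:
            zw, zb, t_new = w_new.copy(), b_new, 1.0
        else:
            zw = w_new + beta * (w_new - w)
            zb = b_new + beta * (b_new - b)
        w, b, t = w_new, b_new, t_new

        if abs(prev_obj - obj) <= tol * max(1.0, abs(obj)):
            stall += 1
            if stall >= 20:
                break
        else:
            stall = 0
        prev_obj = min(prev_obj, obj)

    return w, b, l1svm_objective(X, ys, w, b, C)
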