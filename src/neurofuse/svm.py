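"""Linear max-margin classifier via dual coordinate descent.

Solves the L2-regularised squared-hinge linear SVM

    min_w  1/2 ||w||^2 + C * sum_i max(0, 1 - y_i w.x_i)^2

in the dual, one coordinate at a time (the classic dual coordinate-descent
scheme for linear SVMs, the same algorithm liblinear uses). The intercept is
handled by augmenting patterns with a constant-1 feature, i.e. it is (very
mildly) regularised — again matching liblinear's ``fit_intercept`` handling.

The decoding loops fit one classifier per timepoint per cross-validation
fold per repeat, on a few dozen patterns each; this jitted solver keeps
those inner loops in compiled code. Its solution agrees with
``sklearn.svm.LinearSVC`` (which optimises the identical objective) to
solver tolerance, which the test suite verifies.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["svm_fit", "svm_decision", "svm_fit_predict"]


@njit(cache=True)
def _dual_cd(X, y, C, tol, max_passes):  # pragma: no cover - jitted
    n, d = X.shape
    w = np.zeros(d)
    alpha = np.zeros(n)
    D = 1.0 / (2.0 * C)  # squared-hinge diagonal term
    q = np.empty(n)
    for i in range(n):
        s = D
        for j in range(d):
            s += X[i, j] * X[i, j]
        q[i] = s
    order = np.arange(n)
    state = np.uint64(88172645463325252)
    for _ in range(max_passes):
        # Fisher-Yates shuffle of the coordinate order (deterministic
        # xorshift stream); random sweeps converge far faster than cyclic
        for k in range(n - 1, 0, -1):
            state ^= state << np.uint64(13)
            state ^= state >> np.uint64(7)
            state ^= state << np.uint64(17)
            r = int(state % np.uint64(k + 1))
            tmp = order[k]
            order[k] = order[r]
            order[r] = tmp
        max_pg = 0.0
        for ii in range(n):
            i = order[ii]
            g = -1.0 + D * alpha[i]
            for j in range(d):
                g += y[i] * w[j] * X[i, j]
            if alpha[i] == 0.0:
                pg = g if g < 0.0 else 0.0
            else:
                pg = g
            if pg < -tol or pg > tol:
                old = alpha[i]
                new = old - g / q[i]
                if new < 0.0:
                    new = 0.0
                alpha[i] = new
                step = (new - old) * y[i]
                for j in range(d):
                    w[j] += step * X[i, j]
            apg = -pg if pg < 0.0 else pg
            if apg > max_pg:
                max_pg = apg
        if max_pg < tol:
            break
    return w


def svm_fit(
    train_x: np.ndarray,
    train_y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-4,
    max_passes: int = 500,
) -> np.ndarray:
    """Fit the classifier; ``train_y`` holds class labels {0, 1}.

    Returns the augmented weight vector (last entry is the intercept).
    """
    x = np.ascontiguousarray(train_x, dtype=np.float64)
    xa = np.hstack([x, np.ones((x.shape[0], 1))])
    ypm = np.where(np.asarray(train_y) > 0, 1.0, -1.0)
    return _dual_cd(xa, ypm, C, tol, max_passes)


def svm_decision(w: np.ndarray, test_x: np.ndarray) -> np.ndarray:
    x = np.asarray(test_x, dtype=np.float64)
    return x @ w[:-1] + w[-1]


def svm_fit_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, C: float = 1.0
) -> np.ndarray:
    """Train and predict; a decision score of exactly 0 goes to class 0."""
    w = svm_fit(train_x, train_y, C)
    return (svm_decision(w, test_x) > 0).astype(np.int64)
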