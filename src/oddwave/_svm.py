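"""Batched linear C-SVM dual solver.

Time-resolved decoding trains one tiny max-margin classifier per time point
(typically 8 pseudo-trials x a few hundred whitened sensors, C = 1).  This
module solves the standard C-SVM dual

    min_a  1/2 a' Q a - e' a   s.t.  0 <= a_i <= C,  y' a = 0,
    Q_ij = y_i y_j K_ij

for a whole batch of such problems at once (one per time point, all sharing
the label vector), using synchronized maximal-violating-pair SMO iterations.
The solution is identical to libsvm's (sklearn ``SVC(kernel="linear")``),
which the test suite uses as the independent cross-check; the batched solver
exists because the study pipeline needs on the order of 1e5 fits per decoding
run.
"""

from __future__ import annotations

import numpy as np

__all__ = ["svm_train_batch", "svm_decision"]

_TAU = 1e-12


def svm_train_batch(
    K: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve a batch of C-SVM duals sharing one label vector.

    Parameters
    ----------
    K : (B, n, n) Gram matrices (linear kernel: ``X @ X.T`` per problem).
    y : (n,) labels in {-1, +1}.

    Returns
    -------
    alpha : (B, n) dual coefficients.
    b : (B,) intercepts (decision function is ``sum_i alpha_i y_i K(x_i, x) + b``).
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    if K.ndim != 3 or K.shape[1] != K.shape[2] or K.shape[1] != y.size:
        raise ValueError("K must be (B, n, n) matching the label vector")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be -1/+1")
    B, n, _ = K.shape
    ypos = y > 0

    alpha = np.zeros((B, n))
    G = -np.ones((B, n))  # gradient of the dual objective: Q a - e
    rows = np.arange(B)
    eps = 1e-12

    for _ in range(max_iter):
        yG = -y[None, :] * G  # candidate decision offsets; m = max over I_up
        up = (ypos[None, :] & (alpha < C - eps)) | (~ypos[None, :] & (alpha > eps))
        low = (ypos[None, :] & (alpha > eps)) | (~ypos[None, :] & (alpha < C - eps))
        i = np.argmax(np.where(up, yG, -np.inf), axis=1)
        j = np.argmin(np.where(low, yG, np.inf), axis=1)
        m_val = yG[rows, i]
        big_m = yG[rows, j]
        gap = m_val - big_m
        active = gap > tol
        if not active.any():
            break
        Ki = np.take_along_axis(K, i[:, None, None], axis=2)[:, :, 0]  # (B, n) = K[:, :, i]
        Kj = np.take_along_axis(K, j[:, None, None], axis=2)[:, :, 0]
        eta = np.maximum(Ki[rows, i] + Kj[rows, j] - 2.0 * Ki[rows, j], _TAU)
        s = gap / eta
        # box limits preserving y' a = 0 along the (i, j) working pair
        s_max_i = np.where(y[i] > 0, C - alpha[rows, i], alpha[rows, i])
        s_max_j = np.where(y[j] > 0, alpha[rows, j], C - alpha[rows, j])
        s = np.clip(s, 0.0, np.minimum(s_max_i, s_max_j))
        s = np.where(active, s, 0.0)
        alpha[rows, i] += y[i] * s
        alpha[rows, j] -= y[j] * s
        G += (y[None, :] * s[:, None]) * (Ki - Kj)

    # intercept from the free support vectors (fallback: mid-gap estimate)
    yG = -y[None, :] * G
    free = (alpha > eps) & (alpha < C - eps)
    n_free = free.sum(axis=1)
    with np.errstate(invalid="ignore"):
        b_free = np.where(free, yG, 0.0).sum(axis=1) / np.where(n_free > 0, n_free, 1)
    up = (ypos[None, :] & (alpha < C - eps)) | (~ypos[None, :] & (alpha > eps))
    low = (ypos[None, :] & (alpha > eps)) | (~ypos[None, :] & (alpha < C - eps))
    hi = np.max(np.where(up, yG, -np.inf), axis=1)
    lo = np.min(np.where(low, yG, np.inf), axis=1)
    b_gap = (hi + lo) / 2.0
    b = np.where(n_free > 0, b_free, b_gap)
    return alpha, b


def svm_decision(
    alpha: np.ndarray, b: np.ndarray, y: np.ndarray, K_cross: np.ndarray
) -> np.ndarray:
    """Decision values for test points.

    ``K_cross`` is (B, n, m): kernel between the n training points and m test
    points, per problem.  Returns (B, m).
    """
    coef = alpha * y[None, :]
    return np.einsum("bn,bnm->bm", coef, K_cross) + b[:, None]
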