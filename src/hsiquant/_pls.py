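"""Fast univariate partial least squares (PLS1) regression.

The wavelength-selection wrappers evaluate thousands of small PLS fits
(cross-validated fitness inside the swarm, leave-one-out coefficient
stability in UVE).  This module provides a minimal NIPALS PLS1 with no
per-call validation overhead.  Numerical agreement with
``sklearn.cross_decomposition.PLSRegression(scale=False)`` is asserted in
the test suite; the sklearn estimator remains the user-facing PLSR model
in :mod:`hsiquant.regression`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pls1_fit", "pls1_predict", "kfold_indices", "cv_rmse_pls1"]

_EPS = 1e-12


def pls1_fit(X: np.ndarray, y: np.ndarray, n_components: int):
    """Fit PLS1 on centered data; returns (coef, intercept).

    Components are capped at min(n_components, n_features, n_samples - 1)
    and the deflation loop stops early once the residual X'y weight vector
    vanishes (perfect fit or rank exhaustion).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    k_max = int(min(n_components, p, n - 1))
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    W = np.empty((p, k_max))
    P = np.empty((p, k_max))
    q = np.empty(k_max)
    k = 0
    for a in range(k_max):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn < _EPS:
            break
        w /= wn
        t = Xc @ w
        tt = t @ t
        if tt < _EPS:
            break
        p_a = (Xc.T @ t) / tt
        q_a = (yc @ t) / tt
        Xc -= np.outer(t, p_a)
        yc -= q_a * t
        W[:, k], P[:, k], q[k] = w, p_a, q_a
        k += 1

    if k == 0:
        coef = np.zeros(p)
    else:
        # B = W (P'W)^{-1} q ; P'W is unit upper triangular
        coef = W[:, :k] @ np.linalg.solve(P[:, :k].T @ W[:, :k], q[:k])
    intercept = y_mean - x_mean @ coef
    return coef, intercept


def pls1_predict(X: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    return np.asarray(X, dtype=float) @ coef + intercept


def kfold_indices(n: int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic shuffled k-fold split of range(n)."""
    if k < 2 or k > n:
        raise ValueError(f"cv folds must be in [2, n={n}], got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, test))
    return out


def cv_rmse_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """k-fold cross-validated RMSE of PLS1, pooled over held-out samples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    sq = 0.0
    n = 0
    for train, test in folds:
        coef, icpt = pls1_fit(X[train], y[train], n_components)
        resid = y[test] - pls1_predict(X[test], coef, icpt)
        sq += float(resid @ resid)
        n += test.size
    return float(np.sqrt(sq / n))
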