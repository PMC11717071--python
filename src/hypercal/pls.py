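"""PLS1 regression (NIPALS) with cross-validated RMSECV.

This is the scoring engine behind CARS and UVE wavelength selection: both
rank bands by the magnitude or stability of the PLS regression coefficients.
The fit keeps the whole coefficient path B_1..B_A so cross-validation over
component counts costs one fit per fold rather than one per (fold, a).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["PlsModel", "pls_fit", "pls_predict", "rmsecv", "rmsecv_path"]

log = logging.getLogger(__name__)


@dataclass
class PlsModel:
    """Fitted PLS1 model mapping centered X to centered y.

    ``coefficients`` is the length-p vector for the requested component count;
    ``coef_path[:, a-1]`` holds the coefficients using only the first ``a``
    components (a <= n_components_effective).
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    coef_path: np.ndarray
    n: int
    p: int
    variance_share: np.ndarray  # per-component share of y variance explained

    @property
    def n_components_effective(self) -> int:
        return self.coef_path.shape[1]


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """Fit PLS1 by NIPALS with deflation.

    With ``n_components = rank(X_centered)`` the fitted coefficients reproduce
    the ordinary least-squares solution. Components stop early (with a log
    message) if X deflates to numerical zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("PLS fit needs at least 2 samples")
    if len(y) != n:
        raise ValueError(f"y has length {len(y)}, expected {n}")
    if np.var(y) == 0:
        raise ValueError("y has zero variance; nothing to regress")
    a_max = min(n - 1, p)
    if not 1 <= n_components <= a_max:
        raise ValueError(f"n_components must be in [1, {a_max}], got {n_components}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean
    ss_y = float(yd @ yd)

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    var_share = np.zeros(n_components)
    eps = np.finfo(float).eps
    x_scale = max(np.abs(Xd).max(), eps)

    a_eff = 0
    for a in range(n_components):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn <= 1e3 * eps * x_scale * np.linalg.norm(yd):
            log.debug("PLS deflation exhausted after %d components", a)
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (1e3 * eps * x_scale) ** 2:
            break
        pl = (Xd.T @ t) / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pl)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a] = w, pl, qa
        var_share[a] = (qa * qa * tt) / ss_y if ss_y > 0 else 0.0
        a_eff = a + 1

    if a_eff == 0:
        raise ValueError("X has no usable variance for PLS")

    W, P, q, var_share = W[:, :a_eff], P[:, :a_eff], q[:a_eff], var_share[:a_eff]
    # B_a = W_a (P_a' W_a)^{-1} q_a ; P'W is unit upper-triangular for NIPALS PLS1.
    coef_path = np.zeros((p, a_eff))
    PtW = P.T @ W
    for a in range(1, a_eff + 1):
        sol = np.linalg.solve(PtW[:a, :a], q[:a])
        coef_path[:, a - 1] = W[:, :a] @ sol

    return PlsModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=coef_path[:, -1],
        coef_path=coef_path,
        n=n,
        p=p,
        variance_share=var_share,
    )


def pls_predict(model: PlsModel, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Predict: y_mean + (X - x_mean) @ B. Optionally truncate the path."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.p:
        raise ValueError(f"band count {X.shape[1]} does not match model ({model.p})")
    if n_components is None:
        b = model.coefficients
    else:
        a = min(n_components, model.n_components_effective)
        b = model.coef_path[:, a - 1]
    return model.y_mean + (X - model.x_mean) @ b


def _fold_indices(n: int, k_folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, k_folds)]


def rmsecv_path(
    X: np.ndarray,
    y: np.ndarray,
    a_max: int,
    k_folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """k-fold RMSECV for every component count 1..a_max in one pass.

    Returns an array of length ``min(a_max, feasible)`` where entry ``a-1`` is
    the single RMSE over all n held-out predictions using ``a`` components.
    Infeasible component counts inside a fold are reduced to that fold's
    feasible maximum (logged, never fatal).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 2 <= k_folds <= n:
        raise ValueError(f"k_folds must be in [2, {n}], got {k_folds}")
    a_req = min(a_max, p)
    sq_err = np.zeros(a_req)
    for fold in _fold_indices(n, k_folds, seed):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        a_fold = min(a_req, int(mask.sum()) - 1, p)
        if a_fold < a_req:
            log.debug("fold reduced to %d components (fold size constraint)", a_fold)
        m = pls_fit(X[mask], y[mask], a_fold)
        Xc = X[fold] - m.x_mean
        preds = m.y_mean + Xc @ m.coef_path  # (n_fold, a_eff)
        err = preds - y[fold][:, None]
        per_a = (err**2).sum(axis=0)
        # pad (rank-deficient or reduced folds reuse their largest model)
        padded = np.concatenate([per_a, np.repeat(per_a[-1], a_req - len(per_a))])
        sq_err += padded
    return np.sqrt(sq_err / n)


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    k_folds: int = 10,
    seed: int = 0,
) -> float:
    """k-fold cross-validated RMSE at a single component count."""
    path = rmsecv_path(X, y, a_max=n_components, k_folds=k_folds, seed=seed)
    return float(path[min(n_components, len(path)) - 1])
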