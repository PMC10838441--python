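"""Chemometric comparators: PLSR, random forest, SPA band selection, grid search.

PLSR and random-forest regression go through scikit-learn.  The successive
projections algorithm (SPA) is implemented here: starting from a candidate
band, it repeatedly adds the band whose column has the largest norm after
projection onto the orthogonal complement of the span of the bands already
chosen — a forward selection that favors mutually near-orthogonal
(minimally redundant) wavelengths.  The final subset size is the one with
the smallest cross-validated calibration RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "SPAResult",
    "fit_plsr",
    "predict_plsr",
    "fit_rf",
    "predict_rf",
    "spa_select",
    "grid_search",
    "DEFAULT_RF_TREES",
    "DEFAULT_SPA_SIZE_RANGE",
]

#: number of trees used in the comparison configuration
DEFAULT_RF_TREES = 1500

#: subset sizes searched by SPA
DEFAULT_SPA_SIZE_RANGE = (3, 15)


@dataclass
class SPAResult:
    """Outcome of SPA band selection.

    ``indices`` is the full selection chain in selection order;
    ``selected`` is its prefix of length ``chosen_size``.
    """

    indices: np.ndarray
    error_curve: dict[int, float]
    chosen_size: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("SPA chain contains duplicate indices")
        if self.chosen_size not in self.error_curve:
            raise ValueError("chosen_size must appear in the error curve")

    @property
    def selected(self) -> np.ndarray:
        return self.indices[: self.chosen_size]


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    """Latent-variable (NIPALS) partial least squares regression."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (1 <= n_components <= min(X.shape[0] - 1, X.shape[1])):
        raise ValueError(f"n_components {n_components} out of range for X {X.shape}")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("X has zero variance in every column")
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, y)
    return model


def predict_plsr(model: PLSRegression, X: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(X, dtype=float)).ravel()


def fit_rf(X: np.ndarray, y: np.ndarray, n_trees: int = DEFAULT_RF_TREES,
           seed: int = 0) -> RandomForestRegressor:
    """Bagged regression trees (p/3 features per split, unlimited depth)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    model = RandomForestRegressor(
        n_estimators=n_trees, max_features=1.0 / 3.0, random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    return model


def predict_rf(model: RandomForestRegressor, X: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(X, dtype=float))


def _spa_chain(Xc: np.ndarray, start: int, max_size: int) -> np.ndarray:
    """Projection chain from one start column.

    Maintains the residual matrix R = X - Q Q^T X with Q an orthonormal
    basis of the selected columns; each step picks the column of maximal
    residual norm (skipping numerically collinear columns).
    """
    n, p = Xc.shape
    R = Xc.copy()
    chain = [start]
    tol = 1e-10 * max(np.linalg.norm(Xc, axis=0).max(), 1.0)
    for _ in range(max_size - 1):
        q = R[:, chain[-1]]
        nq = np.linalg.norm(q)
        if nq <= tol:
            break
        q = q / nq
        R -= np.outer(q, q @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        norms[norms <= tol] = -1.0
        best = int(np.argmax(norms))
        if norms[best] < 0:
            break
        chain.append(best)
    return np.asarray(chain, dtype=int)


def _cv_rmse(X: np.ndarray, y: np.ndarray, calibrator, folds: np.ndarray) -> float:
    """Mean of the per-fold validation RMSEs."""
    errs = []
    for f in np.unique(folds):
        tr, va = folds != f, folds == f
        model = calibrator(X[tr], y[tr])
        pred = np.asarray(model.predict(X[va])).ravel()
        errs.append(float(np.sqrt(np.mean((pred - y[va]) ** 2))))
    return float(np.mean(errs))


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    size_range: tuple[int, int] = DEFAULT_SPA_SIZE_RANGE,
    calibrator=None,
    starts=None,
    n_cv_folds: int = 5,
    seed: int = 0,
) -> SPAResult:
    """SPA wavelength selection with calibration-based subset-size choice.

    Every column is tried as the chain start (restrict with ``starts``);
    for each chain, subset sizes in ``size_range`` are scored by
    ``n_cv_folds``-fold cross-validated RMSE of the calibrator (default:
    PLSR with as many components as selected bands, i.e. an MLR-equivalent
    fit), and the overall best (chain, size) wins.  Ties break toward the
    smaller subset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    lo, hi = size_range
    if not (1 <= lo <= hi <= p):
        raise ValueError(f"size_range {size_range} outside [1, {p}]")
    Xc = X - X.mean(axis=0)  # column-centered internally
    if calibrator is None:
        def calibrator(Xtr, ytr):
            ncomp = max(1, min(Xtr.shape[1], Xtr.shape[0] - 1))
            m = PLSRegression(n_components=ncomp, scale=False)
            m.fit(Xtr, ytr)
            return m
    rng = np.random.default_rng(seed)
    folds = rng.permutation(np.arange(n) % n_cv_folds)
    if starts is None:
        starts = range(p)
    best = None  # (rmse, size, chain, curve)
    for s in starts:
        chain = _spa_chain(Xc, int(s), hi)
        if chain.size < lo:
            continue
        curve = {}
        for size in range(lo, min(hi, chain.size) + 1):
            idx = chain[:size]
            curve[size] = _cv_rmse(X[:, idx], y, calibrator, folds)
        size_best = min(curve, key=lambda k: (curve[k], k))
        cand = (curve[size_best], size_best, chain, curve)
        if best is None or cand[0] < best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    if best is None:
        raise ValueError("no SPA chain reached the minimum subset size")
    rmse, size, chain, curve = best
    return SPAResult(indices=chain, error_curve=curve, chosen_size=size)


def grid_search(method, param_grid: dict, X: np.ndarray, y: np.ndarray,
                folds: np.ndarray) -> dict:
    """Pick the parameter set minimizing mean validation RMSE over folds.

    ``method(X_train, y_train, **params)`` must return a fitted model with a
    ``predict`` method.  Ties break toward the smaller parameter value
    (grid-order independent).
    """
    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise ValueError("parameter grid is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    keys = sorted(param_grid)
    from itertools import product

    best = None
    for combo in sorted(product(*(sorted(param_grid[k]) for k in keys))):
        params = dict(zip(keys, combo))
        rmse = _cv_rmse(X, y, lambda Xtr, ytr: method(Xtr, ytr, **params), folds)
        if best is None or rmse < best[0]:
            best = (rmse, params)
    return best[1]
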