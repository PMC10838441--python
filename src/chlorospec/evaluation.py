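"""Cross-validation harness, metrics and method-comparison tables.

Metrics follow the usual chemometric definitions:

    RMSE  = sqrt(mean((y_i - k_i)^2))
    NRMSE = RMSE / mean(y)            (normalized by the ground-truth mean)
    R^2   = 1 - sum((y_i - k_i)^2) / sum((y_i - ybar)^2)

with y the measured SPAD values and k the predictions.  ``run_cv`` trains
each method on k-1 folds and evaluates on the held-out fold, producing a
per-fold table with a final "Average" row (the unweighted mean of the fold
rows).  All data-dependent choices — min-max scaling (per sample),
augmentation, SPA band selection, grid-search tuning — happen inside each
training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import attention_net, baselines, preprocess
from .synthetic_data import LabeledDataset

__all__ = [
    "FoldMetrics",
    "kfold_split",
    "compute_metrics",
    "run_cv",
    "METHODS",
    "plot_predictions",
    "plot_attention",
]


@dataclass(frozen=True)
class FoldMetrics:
    """RMSE / NRMSE / R^2 for one validation fold."""

    fold: int | str
    rmse: float
    nrmse: float
    r2: float


def kfold_split(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Shuffled partition into k near-equal folds; returns fold ids in 1..k.

    Fold sizes differ by at most one (478 samples over 5 folds gives sizes
    96, 96, 96, 95, 95).  Deterministic per seed.
    """
    if k < 2:
        raise ValueError("need k >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    base, extra = divmod(n, k)
    start = 0
    for fold in range(1, k + 1):
        size = base + (1 if fold <= extra else 0)
        assignment[order[start:start + size]] = fold
        start += size
    return assignment


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray, fold: int | str = 0) -> FoldMetrics:
    """RMSE, NRMSE and R^2 for one set of predictions."""
    y = np.asarray(y_true, dtype=float)
    k = np.asarray(y_pred, dtype=float)
    if y.size == 0 or y.shape != k.shape:
        raise ValueError("y_true and y_pred must be equal-length non-empty vectors")
    rmse = float(np.sqrt(np.mean((y - k) ** 2)))
    ybar = float(y.mean())
    if ybar == 0:
        raise ValueError("NRMSE undefined: mean of ground truth is zero")
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant ground truth")
    r2 = 1.0 - float(np.sum((y - k) ** 2)) / ss_tot
    return FoldMetrics(fold=fold, rmse=rmse, nrmse=rmse / ybar, r2=r2)


# --------------------------------------------------------------------------
# per-method training/prediction pipelines (train-fold-only fitting)
# --------------------------------------------------------------------------

#: default grid-search range for PLSR latent components
PLSR_COMPONENT_GRID = tuple(range(1, 16))


def _scale_rows(X: np.ndarray) -> np.ndarray:
    return preprocess.minmax_scale_dataset(X, axis=1)


def _fdr_rows(X: np.ndarray, grid) -> np.ndarray:
    return preprocess.first_derivative(X, grid)


def _cnn_predict(Xtr, ytr, Xva, config: dict, seed: int, use_attention: bool):
    n_bands = Xtr.shape[1]
    cfg = attention_net.ModelConfig(
        n_bands=n_bands, use_attention=use_attention, seed=seed,
        **{k: v for k, v in config.items() if k not in ("n_bands", "use_attention", "seed")},
    )
    model = attention_net.build_model(cfg)
    augment = preprocess.AugmentationConfig()
    model, _ = attention_net.train(model, (Xtr, ytr), cfg=cfg, augment=augment)
    return model.predict(Xva)


def _linear_models_predict(method_key, Xtr, ytr, Xva, config, seed):
    inner_folds = kfold_split(len(ytr), k=config.get("inner_folds", 5), seed=seed)
    use_spa = "spa" in method_key
    if use_spa:
        spa = baselines.spa_select(
            Xtr, ytr,
            size_range=config.get("spa_size_range", baselines.DEFAULT_SPA_SIZE_RANGE),
            starts=config.get("spa_starts"),
            seed=seed,
        )
        Xtr, Xva = Xtr[:, spa.selected], Xva[:, spa.selected]
    if method_key.startswith("plsr"):
        grid = [c for c in config.get("plsr_components", PLSR_COMPONENT_GRID)
                if c <= min(Xtr.shape[0] - 1, Xtr.shape[1])]
        best = baselines.grid_search(
            lambda Xt, yt, n_components: baselines.fit_plsr(Xt, yt, n_components),
            {"n_components": grid}, Xtr, ytr, inner_folds,
        )
        model = baselines.fit_plsr(Xtr, ytr, **best)
        return baselines.predict_plsr(model, Xva)
    model = baselines.fit_rf(Xtr, ytr, n_trees=config.get("rf_trees", baselines.DEFAULT_RF_TREES),
                             seed=seed)
    return baselines.predict_rf(model, Xva)


METHODS = (
    "cnn_attention", "cnn_plain",
    "plsr_full", "rf_full",
    "plsr_spa", "rf_spa",
    "plsr_spa_fdr", "rf_spa_fdr",
)


def run_cv(
    dataset: LabeledDataset,
    method: str,
    config: dict | None = None,
    seed: int = 0,
    k: int = 5,
) -> pd.DataFrame:
    """k-fold cross-validate one method; returns the per-fold metrics table.

    The table has k rows (folds 1..k) plus an "Average" row holding the
    arithmetic mean of the fold metrics.  ``config`` tunes per-method
    settings (e.g. ``epochs`` for the CNNs, ``spa_starts`` / ``rf_trees``
    for the baselines); the defaults reproduce the comparison design.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    config = dict(config or {})
    folds = dataset.folds if dataset.folds is not None else kfold_split(len(dataset), k, seed)
    k = int(folds.max())

    use_fdr = method.endswith("_fdr")
    rows = []
    for fold in range(1, k + 1):
        tr, va = folds != fold, folds == fold
        Xtr_raw, Xva_raw = dataset.X[tr], dataset.X[va]
        ytr, yva = dataset.y[tr], dataset.y[va]
        if use_fdr:
            Xtr_raw = _fdr_rows(Xtr_raw, dataset.grid)
            Xva_raw = _fdr_rows(Xva_raw, dataset.grid)
        Xtr, Xva = _scale_rows(Xtr_raw), _scale_rows(Xva_raw)
        fold_seed = seed * 1000 + fold
        if method == "cnn_attention":
            pred = _cnn_predict(Xtr, ytr, Xva, config, fold_seed, use_attention=True)
        elif method == "cnn_plain":
            pred = _cnn_predict(Xtr, ytr, Xva, config, fold_seed, use_attention=False)
        else:
            pred = _linear_models_predict(method, Xtr, ytr, Xva, config, fold_seed)
        rows.append(compute_metrics(yva, pred, fold=fold))

    table = pd.DataFrame(
        [{"fold": str(m.fold), "rmse": m.rmse, "nrmse": m.nrmse, "r2": m.r2} for m in rows]
    )
    avg = table[["rmse", "nrmse", "r2"]].mean()
    table.loc[len(table)] = {"fold": "Average", **avg.to_dict()}
    return table


# --------------------------------------------------------------------------
# plotting (predicted-vs-measured scatter, attention-weight curve)
# --------------------------------------------------------------------------

def plot_predictions(y_true, y_pred, ax=None, title: str | None = None):
    """Scatter of predicted vs. measured SPAD with the 1:1 line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    m = compute_metrics(y_true, y_pred)
    ax.scatter(y_true, y_pred, s=12, alpha=0.7)
    lims = [min(np.min(y_true), np.min(y_pred)), max(np.max(y_true), np.max(y_pred))]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("Measured SPAD")
    ax.set_ylabel("Predicted SPAD")
    ax.set_title(title or f"R$^2$={m.r2:.3f}, RMSE={m.rmse:.3f}")
    return ax


def plot_attention(weights, grid, ax=None):
    """Attention-weight curve over wavelength."""
    import matplotlib.pyplot as plt

    values = getattr(weights, "values", weights)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(grid.wavelengths_nm, values)
    ax.set_xlabel("Wavelength (nm)")
    ax.set_ylabel("Attention weight")
    ax.set_ylim(0, 1)
    return ax
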