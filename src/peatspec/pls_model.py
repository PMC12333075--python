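"""PLS1 regression for predicting alpha-diversity from plot spectra.

Reflectance predictors are massively collinear (neighbouring wavelengths
carry nearly the same signal), so ordinary least squares is hopeless and
partial least squares is the standard remedy: components are extracted to
maximize covariance with the response, and only the first few are kept.

This module implements NIPALS PLS1 on centred (and, by default,
unit-variance-scaled) predictors with a centred response, selects the
component count by 10-fold cross-validated PRESS, and evaluates a final
model on a held-out 30% split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evaluation import FitMetrics, fit_metrics

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    """A fitted PLS1 model.

    ``coef_`` and ``intercept_`` act on predictors in their original
    units; ``x_weights_`` / ``x_loadings_`` / ``x_scores_`` are the
    per-component NIPALS vectors on the standardized scale.
    """

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    x_weights_: np.ndarray   # (p, k)
    x_loadings_: np.ndarray  # (p, k)
    y_loadings_: np.ndarray  # (k,)
    x_scores_: np.ndarray    # (n, k)
    coef_: np.ndarray        # (p,) original units
    intercept_: float
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def pls_fit(X, y, n_components: int, scale: bool = True) -> PLSModel:
    """Fit PLS1 by NIPALS with per-component deflation.

    Predictors are centred and (if ``scale``) divided by their sample
    standard deviation (ddof=1); the response is centred.  Coefficients
    are mapped back to the original predictor units.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ConfigError("X rows must match y length")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ConfigError(
            f"n_components={n_components} outside [1, min(n-1, p)]={min(n - 1, p)}"
        )
    if np.std(y) == 0:
        raise ConfigError("constant response: PLS undefined")
    x_mean = X.mean(axis=0)
    if scale and n > 1:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(p)
    y_mean = float(y.mean())
    Xc = (X - x_mean) / x_scale
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xd, yd = Xc.copy(), yc.copy()
    y_norm0 = float(np.linalg.norm(yc))
    for k in range(n_components):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn <= max(1e-12 * y_norm0, 1e3 * _EPS):
            raise ConfigError(
                f"component {k + 1} exceeds the rank of the deflated data"
            )
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e3 * _EPS:
            raise ConfigError(
                f"component {k + 1} exceeds the rank of the deflated data"
            )
        qk = float(t @ yd) / tt
        pk = (Xd.T @ t) / tt
        Xd = Xd - np.outer(t, pk)
        yd = yd - qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, pk, qk, t

    # B = W (P^T W)^{-1} q on the standardized scale
    B = W @ np.linalg.solve(P.T @ W, q)
    coef = B / x_scale
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        x_weights_=W,
        x_loadings_=P,
        y_loadings_=q,
        x_scores_=T,
        coef_=coef,
        intercept_=intercept,
    )


def _fold_assignment(n: int, k_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random balanced fold labels in {0..k_folds-1}."""
    labels = np.arange(n) % k_folds
    return labels[rng.permutation(n)]


def cv_select_components(
    X,
    y,
    k_folds: int = 10,
    max_components: int | None = None,
    seed: int | np.random.Generator = 0,
    scale: bool = True,
) -> tuple[int, pd.DataFrame]:
    """Pick the component count minimizing cross-validated PRESS.

    Folds are a seeded random partition; candidates run 1..max_components
    (default: the largest count every training fold supports); ties go to
    the smaller count.  Returns ``(n_components, cv_table)`` where the
    table has one row per candidate with its PRESS and CV-RMSE.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if k_folds < 2 or k_folds > n:
        raise ConfigError(f"k_folds={k_folds} must be in [2, n={n}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = _fold_assignment(n, k_folds, rng)
    min_train = min(int(np.sum(folds != f)) for f in range(k_folds))
    cap = min(min_train - 1, X.shape[1])
    if max_components is None:
        max_components = cap
    max_components = min(max_components, cap)
    if max_components < 1:
        raise ConfigError("folds too small to fit even one component")

    press = np.zeros(max_components)
    counts_ok = np.ones(max_components, dtype=bool)
    for f in range(k_folds):
        test = folds == f
        Xtr, ytr = X[~test], y[~test]
        Xte, yte = X[test], y[test]
        for k in range(1, max_components + 1):
            try:
                model = pls_fit(Xtr, ytr, k, scale=scale)
            except ConfigError:
                counts_ok[k - 1 :] = False
                break
            press[k - 1] += float(np.sum((model.predict(Xte) - yte) ** 2))
    if not counts_ok.any():
        raise ConfigError("no candidate component count could be fitted")
    press = press[counts_ok]
    candidates = np.arange(1, max_components + 1)[counts_ok]
    best = int(candidates[np.argmin(press)])  # argmin takes the first = smallest
    cv_table = pd.DataFrame(
        {
            "n_components": candidates,
            "press": press,
            "rmse_cv": np.sqrt(press / n),
        }
    )
    return best, cv_table


@dataclass
class DiversityModelResult:
    """Outcome of the 70/30 train/test evaluation of a diversity model."""

    model: PLSModel
    n_components: int
    cv_table: pd.DataFrame
    metrics: FitMetrics
    predictions: pd.DataFrame  # columns: index, observed, predicted, split


def evaluate_diversity_model(
    X,
    y,
    train_fraction: float = 0.7,
    seed: int = 0,
    k_folds: int = 10,
    max_components: int | None = None,
    scale: bool = True,
) -> DiversityModelResult:
    """Train/test evaluation of a spectra -> diversity PLS model.

    A seeded random split reserves ``1 - train_fraction`` of the plots as
    test data; the component count is chosen by k-fold CV *on the training
    set only*; metrics (R2/RMSE/bias) are computed on the held-out plots.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 10:
        raise ConfigError("need at least 10 samples for a 70/30 evaluation")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    if n_train < k_folds or n_train >= n:
        raise ConfigError("train fraction leaves too few samples on one side")
    train_idx, test_idx = order[:n_train], order[n_train:]
    n_comp, cv_table = cv_select_components(
        X[train_idx], y[train_idx], k_folds=k_folds,
        max_components=max_components, seed=rng, scale=scale,
    )
    model = pls_fit(X[train_idx], y[train_idx], n_comp, scale=scale)
    model.cv_table = cv_table
    pred_test = model.predict(X[test_idx])
    metrics = fit_metrics(y[test_idx], pred_test)
    predictions = pd.DataFrame(
        {
            "index": np.concatenate([train_idx, test_idx]),
            "observed": np.concatenate([y[train_idx], y[test_idx]]),
            "predicted": np.concatenate([model.predict(X[train_idx]), pred_test]),
            "split": ["train"] * n_train + ["test"] * (n - n_train),
        }
    )
    return DiversityModelResult(
        model=model,
        n_components=n_comp,
        cv_table=cv_table,
        metrics=metrics,
        predictions=predictions,
    )
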