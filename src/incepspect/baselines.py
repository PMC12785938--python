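"""PLSR and SVR calibration models with cross-validated tuning.

PLSR searches the latent-variable count (default range 5-20) by 5-fold
RMSECV; SVR (RBF) runs a two-step grid search over (C, gamma) with
calibration-fitted z-scoring of the predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .spectra_core import SpectraSet

__all__ = [
    "PlsrModel",
    "SvrModel",
    "fit_plsr_cv",
    "fit_svr_gridsearch",
    "predict",
    "DEFAULT_LV_RANGE",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

DEFAULT_LV_RANGE = (5, 20)
DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0, 1000.0)
DEFAULT_GAMMA_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class PlsrModel:
    n_latent: int
    estimator: PLSRegression
    rmsecv_curve: dict[int, float] = field(default_factory=dict)
    n_features: int = 0


@dataclass
class SvrModel:
    C: float
    gamma: float
    estimator: SVR
    x_mean: np.ndarray = None  # type: ignore[assignment]
    x_scale: np.ndarray = None  # type: ignore[assignment]
    n_features: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


def _cv_rmse(make_est, X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    resid = np.empty_like(y)
    for tr, te in kf.split(X):
        est = make_est()
        est.fit(X[tr], y[tr])
        resid[te] = y[te] - np.asarray(est.predict(X[te])).ravel()
    return float(np.sqrt(np.mean(resid**2)))


def fit_plsr_cv(
    calibration: SpectraSet,
    lv_range: tuple[int, int] = DEFAULT_LV_RANGE,
    folds: int = 5,
    seed: int = 0,
) -> PlsrModel:
    """Select the LV count minimizing k-fold RMSECV (ties -> fewer LVs) and
    refit on all calibration rows."""
    X, y = calibration.absorbance, calibration.target
    n, p = X.shape
    if n <= folds:
        raise ValueError("need more samples than folds")
    lo, hi = lv_range
    hi = min(hi, n - 1 - (n // folds), p)  # feasible inside every CV fold
    if lo > hi:
        raise ValueError(f"latent-variable range [{lv_range[0]}, {lv_range[1]}] infeasible for n={n}, p={p}")
    curve: dict[int, float] = {}
    for lv in range(lo, hi + 1):
        curve[lv] = _cv_rmse(lambda: PLSRegression(n_components=lv, scale=False), X, y, folds, seed)
    best_lv = min(curve, key=lambda lv: (curve[lv], lv))
    est = PLSRegression(n_components=best_lv, scale=False)
    est.fit(X, y)
    return PlsrModel(n_latent=best_lv, estimator=est, rmsecv_curve=curve, n_features=p)


def _refine_grid(value: float, grid: np.ndarray, n_points: int = 5) -> np.ndarray:
    """Log-spaced points spanning one decade centred on ``value``."""
    lo = np.log10(value) - 0.5
    hi = np.log10(value) + 0.5
    return np.unique(np.concatenate([10.0 ** np.linspace(lo, hi, n_points), [value]]))


def fit_svr_gridsearch(
    calibration: SpectraSet,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> SvrModel:
    """Two-step (coarse then refined) grid search over (C, gamma) scored by
    k-fold RMSECV; predictors z-scored with calibration statistics."""
    C_grid = np.asarray(C_grid, dtype=float)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if C_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("grids must be non-empty")
    X, y = calibration.absorbance, calibration.target
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd

    def search(Cs, gammas):
        best = (np.inf, None, None)
        for C in Cs:
            for g in gammas:
                score = _cv_rmse(lambda: SVR(kernel="rbf", C=C, gamma=g), Z, y, folds, seed)
                if score < best[0]:
                    best = (score, C, g)
        return best

    _, C1, g1 = search(C_grid, gamma_grid)
    if C_grid.size > 1 or gamma_grid.size > 1:
        _, C2, g2 = search(_refine_grid(C1, C_grid), _refine_grid(g1, gamma_grid))
    else:
        C2, g2 = C1, g1
    est = SVR(kernel="rbf", C=C2, gamma=g2)
    est.fit(Z, y)
    return SvrModel(C=float(C2), gamma=float(g2), estimator=est,
                    x_mean=mu, x_scale=sd, n_features=X.shape[1])


def predict(model: PlsrModel | SvrModel, data: SpectraSet) -> np.ndarray:
    """One unclipped prediction per row."""
    X = data.absorbance
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model was fit on {model.n_features} variables, data has {X.shape[1]}"
        )
    if isinstance(model, SvrModel):
        X = (X - model.x_mean) / model.x_scale
    return np.asarray(model.estimator.predict(X)).ravel()
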