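"""CARS and SPA wavelength selection.

CARS runs Monte-Carlo PLS fits with an exponentially decaying enforced
retention (EDF) plus adaptive reweighted sampling among the survivors, and
keeps the subset with minimal cross-validated RMSE. SPA grows chains of
minimally collinear columns by successive orthogonal projections and scores
candidate chains by cross-validated MLR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .spectra_core import SpectraSet

__all__ = ["VariableSubset", "edf_ratio", "cars_select", "spa_select"]


@dataclass(frozen=True)
class VariableSubset:
    """Selected wavelength indices with provenance and RMSECV score."""

    indices: np.ndarray
    provenance: str  # {"cars", "spa", "full"}
    score: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise ValueError("variable subset must be non-empty")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("indices must be unique and sorted")
        if idx[0] < 0:
            raise ValueError("indices must be non-negative")
        if self.provenance not in {"cars", "spa", "full"}:
            raise ValueError(f"unknown provenance '{self.provenance}'")


def edf_ratio(run_index: int, total_runs: int, p: int) -> float:
    """Exponentially decreasing retained-variable fraction.

    r_i = a * exp(-k * i) with a, k fixed by r_1 = 1 and r_N = 2/p.
    """
    if not 1 <= run_index <= total_runs:
        raise ValueError("run_index must lie in [1, total_runs]")
    if p <= 2:
        raise ValueError("p must exceed 2")
    if total_runs < 2:
        return 1.0
    a = (p / 2.0) ** (1.0 / (total_runs - 1))
    k = np.log(p / 2.0) / (total_runs - 1)
    return float(a * np.exp(-k * run_index))


def _pls_coefficients(X: np.ndarray, y: np.ndarray, max_components: int) -> np.ndarray:
    """|b| from a PLS fit on autoscaled data."""
    ncomp = min(max_components, X.shape[0] - 1, X.shape[1], int(np.linalg.matrix_rank(X)))
    ncomp = max(1, ncomp)
    pls = PLSRegression(n_components=ncomp, scale=True)
    pls.fit(X, y)
    return np.abs(pls.coef_.ravel())


def _subset_rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    cols: np.ndarray,
    folds: int,
    seed: int,
    model: str = "pls",
    max_components: int = 10,
) -> float:
    """Pooled k-fold RMSE of a PLS (or MLR) model on the column subset."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    resid = np.empty_like(y)
    Xs = X[:, cols]
    for tr, te in kf.split(Xs):
        if model == "pls":
            ncomp = max(1, min(max_components, len(tr) - 1, Xs.shape[1]))
            est = PLSRegression(n_components=ncomp, scale=True)
        else:
            est = LinearRegression()
        est.fit(Xs[tr], y[tr])
        resid[te] = y[te] - np.asarray(est.predict(Xs[te])).ravel()
    return float(np.sqrt(np.mean(resid**2)))


def cars_select(
    calibration: SpectraSet,
    mc_runs: int = 50,
    folds: int = 5,
    seed: int = 0,
    row_fraction: float = 0.8,
    max_components: int = 10,
) -> VariableSubset:
    """Competitive adaptive reweighted sampling.

    Per run: fit PLS on a Monte-Carlo row subsample restricted to currently
    retained variables, weight variables by |coefficient|, keep the EDF-forced
    count of top-weighted variables, then resample among them in proportion to
    weight. Each run's retained set is scored by ``folds``-fold RMSECV on the
    full calibration set; the minimal-score set wins.
    """
    X = calibration.absorbance
    y = calibration.target
    n, p = X.shape
    if n < folds:
        raise ValueError("calibration must have at least `folds` samples")
    if p < 3:
        raise ValueError("need at least 3 variables")
    rng = np.random.default_rng(seed)
    n_sub = max(folds, int(round(row_fraction * n)))

    retained = np.arange(p)
    best_idx, best_score = None, np.inf
    for i in range(1, mc_runs + 1):
        rows = rng.choice(n, size=n_sub, replace=False)
        w = _pls_coefficients(X[np.ix_(rows, retained)], y[rows], max_components)
        if not np.any(w > 0):
            raise ValueError("degenerate PLS fit: all coefficients zero")
        n_keep = max(2, min(retained.size, int(np.ceil(edf_ratio(i, mc_runs, p) * p))))
        order = np.argsort(-w, kind="stable")
        forced = retained[order[:n_keep]]
        forced_w = w[order[:n_keep]]
        # adaptive reweighted sampling: weighted draws with replacement,
        # survivors = unique draws
        probs = forced_w / forced_w.sum()
        draws = rng.choice(forced.size, size=forced.size, replace=True, p=probs)
        survivors = np.unique(forced[np.unique(draws)])
        if survivors.size < 2:
            survivors = np.sort(forced[:2])
        retained = np.sort(survivors)
        score = _subset_rmsecv(X, y, retained, folds, seed, "pls", max_components)
        if score < best_score:
            best_score, best_idx = score, retained.copy()
    return VariableSubset(indices=best_idx, provenance="cars", score=best_score)


def _spa_chain(X: np.ndarray, start: int, max_vars: int) -> list[int]:
    """Greedy successive-projection chain from one start column.

    At each step every remaining column is projected onto the orthogonal
    complement of the span of the selected columns; the largest projected
    norm wins. Stops early if all projected norms vanish (rank deficiency).
    """
    n, p = X.shape
    chain = [start]
    P = X.copy().astype(float)
    # orthogonalize against the start column
    for _ in range(1, max_vars):
        v = P[:, chain[-1]].copy()
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break
        v /= nv
        P = P - np.outer(v, v @ P)
        norms = np.linalg.norm(P, axis=0)
        norms[chain] = -1.0
        best = int(np.argmax(norms))
        if norms[best] < 1e-10:
            break
        chain.append(best)
    return chain


def spa_select(
    calibration: SpectraSet,
    min_vars: int = 2,
    max_vars: int | None = None,
    folds: int = 5,
    seed: int = 0,
) -> VariableSubset:
    """Successive projections algorithm.

    Builds a projection chain from every start column, then picks the (start,
    chain-length) pair with minimal cross-validated MLR RMSE.
    """
    X = calibration.absorbance
    y = calibration.target
    n, p = X.shape
    if max_vars is None:
        max_vars = min(n - 1, p, 30)
    if not 1 <= min_vars <= max_vars <= min(n - 1, p):
        raise ValueError("require 1 <= min_vars <= max_vars <= min(n-1, p)")

    best_idx, best_score = None, np.inf
    for start in range(p):
        chain = _spa_chain(X, start, max_vars)
        for L in range(min_vars, len(chain) + 1):
            cols = np.sort(np.array(chain[:L], dtype=int))
            score = _subset_rmsecv(X, y, cols, folds, seed, model="mlr")
            if score < best_score:
                best_score, best_idx = score, cols
    return VariableSubset(indices=best_idx, provenance="spa", score=best_score)
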