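"""Scatter correction (MSC, SNV), min-max normalization and SPXY
calibration/prediction partitioning.

All fitted statistics come from calibration rows only; transforms carry a
provenance flag so leakage is detectable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .spectra_core import SpectraSet

__all__ = [
    "FittedTransform",
    "SplitResult",
    "snv",
    "snv_set",
    "msc_fit",
    "msc_apply",
    "minmax_fit",
    "minmax_apply",
    "identity_transform",
    "apply_transform",
    "spxy_split",
    "split_multi",
]


@dataclass(frozen=True)
class FittedTransform:
    """A preprocessing transform with calibration-fitted parameters.

    ``kind`` is one of {"minmax_normalize", "msc", "snv", "identity"};
    ``parameters`` holds the per-kind fitted values. ``fit_on_calibration``
    records provenance and is asserted by :func:`apply_transform`.
    """

    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)
    fit_on_calibration: bool = True

    def __post_init__(self) -> None:
        if self.kind not in {"minmax_normalize", "msc", "snv", "identity"}:
            raise ValueError(f"unknown transform kind '{self.kind}'")


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/prediction index partition."""

    calibration_idx: np.ndarray
    prediction_idx: np.ndarray

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_idx, dtype=int)
        pred = np.asarray(self.prediction_idx, dtype=int)
        object.__setattr__(self, "calibration_idx", cal)
        object.__setattr__(self, "prediction_idx", pred)
        if cal.size == 0 or pred.size == 0:
            raise ValueError("both subsets must be non-empty")
        if np.intersect1d(cal, pred).size:
            raise ValueError("calibration and prediction indices overlap")

    @property
    def n_total(self) -> int:
        return self.calibration_idx.size + self.prediction_idx.size


# ---------------------------------------------------------------------------
# spectrum-wise corrections


def snv(spectrum: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to mean 0,
    sample (``ddof=1``) standard deviation 1."""
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("snv needs a 1-D vector of length >= 2")
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("constant spectrum has zero variance")
    return (x - x.mean()) / sd


def snv_set(data: SpectraSet, ddof: int = 1) -> SpectraSet:
    """Apply SNV row-wise to a whole set."""
    A = data.absorbance
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum has zero variance")
    return data.with_absorbance((A - mu) / sd)


def msc_fit(calibration: SpectraSet) -> FittedTransform:
    """Fit multiplicative scatter correction: reference = mean calibration
    spectrum."""
    if calibration.n_samples == 0:
        raise ValueError("calibration set is empty")
    reference = calibration.absorbance.mean(axis=0)
    return FittedTransform(kind="msc", parameters={"reference": reference})


def msc_apply(transform: FittedTransform, spectrum: np.ndarray) -> np.ndarray:
    """Correct one spectrum: least-squares x ~= a + b*r, return (x - a)/b."""
    if transform.kind != "msc":
        raise ValueError("transform is not an MSC fit")
    r = transform.parameters["reference"]
    x = np.asarray(spectrum, dtype=float)
    if x.shape != r.shape:
        raise ValueError("spectrum length does not match MSC reference")
    b, a = np.polyfit(r, x, 1)
    if b == 0:
        raise ValueError("degenerate MSC fit: zero slope")
    return (x - a) / b


def msc_apply_set(transform: FittedTransform, data: SpectraSet) -> SpectraSet:
    out = np.vstack([msc_apply(transform, row) for row in data.absorbance])
    return data.with_absorbance(out)


# ---------------------------------------------------------------------------
# per-variable min-max normalization


def minmax_fit(calibration: SpectraSet) -> FittedTransform:
    """Per-wavelength min/max from calibration rows only."""
    A = calibration.absorbance
    return FittedTransform(
        kind="minmax_normalize",
        parameters={"min": A.min(axis=0), "max": A.max(axis=0)},
    )


def minmax_apply(transform: FittedTransform, data: SpectraSet) -> SpectraSet:
    """Map columns through the calibration min/max; constant calibration
    columns pass through as zeros, prediction values may leave [0, 1]."""
    if transform.kind != "minmax_normalize":
        raise ValueError("transform is not a min-max fit")
    lo = transform.parameters["min"]
    hi = transform.parameters["max"]
    rng = hi - lo
    safe = np.where(rng > 0, rng, 1.0)
    scaled = np.where(rng > 0, (data.absorbance - lo) / safe, 0.0)
    return data.with_absorbance(scaled)


def identity_transform() -> FittedTransform:
    return FittedTransform(kind="identity")


def apply_transform(transform: FittedTransform, data: SpectraSet) -> SpectraSet:
    """Dispatch on transform kind; checks the calibration-provenance flag."""
    if not transform.fit_on_calibration:
        raise ValueError("refusing to apply a transform not fit on calibration data")
    if transform.kind == "identity":
        return data
    if transform.kind == "snv":
        return snv_set(data)
    if transform.kind == "msc":
        return msc_apply_set(transform, data)
    if transform.kind == "minmax_normalize":
        return minmax_apply(transform, data)
    raise ValueError(f"unknown transform kind '{transform.kind}'")


def fit_transform_chain(calibration: SpectraSet, kinds: list[str]) -> list[FittedTransform]:
    """Fit a sequence of transforms on calibration data, each on the output
    of the previous one."""
    fitted = []
    cur = calibration
    for kind in kinds:
        if kind == "snv":
            t = FittedTransform(kind="snv")
        elif kind == "msc":
            t = msc_fit(cur)
        elif kind == "minmax_normalize":
            t = minmax_fit(cur)
        elif kind == "identity":
            t = identity_transform()
        else:
            raise ValueError(f"unknown transform kind '{kind}'")
        fitted.append(t)
        cur = apply_transform(t, cur)
    return fitted


def apply_transform_chain(transforms: list[FittedTransform], data: SpectraSet) -> SpectraSet:
    for t in transforms:
        data = apply_transform(t, data)
    return data


# ---------------------------------------------------------------------------
# SPXY partitioning


def _joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(i,j) = dx(i,j)/max dx + dy(i,j)/max dy, Euclidean on X, |dy| on y."""
    from scipy.spatial.distance import squareform, pdist

    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    mx, my = dx.max(), dy.max()
    if mx == 0 and my == 0:
        raise ValueError("all samples identical: SPXY distances are all zero")
    d = np.zeros_like(dx)
    if mx > 0:
        d += dx / mx
    if my > 0:
        d += dy / my
    return d


def spxy_split(data: SpectraSet, calibration_fraction: float = 0.8) -> SplitResult:
    """Kennard-Stone max-min selection on joint X-Y distances.

    Seeds with the pair at maximal joint distance, then repeatedly adds the
    sample maximizing its minimum distance to the selected set, until
    ``floor(fraction * n)`` (at least 2) calibration samples are chosen.
    Ties break toward the lowest index.
    """
    n = data.n_samples
    if not 0.0 < calibration_fraction < 1.0:
        raise ValueError("calibration_fraction must be in (0, 1)")
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_cal = max(2, int(np.floor(calibration_fraction * n)))
    if n_cal >= n:
        raise ValueError("calibration fraction leaves no prediction samples")

    d = _joint_distance_matrix(data.absorbance, data.target)
    # seed pair: maximal distance, ties -> lexicographically smallest (i, j)
    flat = np.argmax(d)  # row-major argmax is the lowest-index tie winner
    i0, j0 = np.unravel_index(flat, d.shape)
    selected = [min(i0, j0), max(i0, j0)]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False

    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_cal:
        masked = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(masked))  # argmax returns first (lowest) index on ties
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, d[nxt])

    cal = np.array(sorted(selected), dtype=int)
    pred = np.flatnonzero(remaining)
    return SplitResult(calibration_idx=cal, prediction_idx=pred)


def split_multi(data: SpectraSet, fraction: float = 0.8) -> SplitResult:
    """Independent SPXY within each adulterant group, merged."""
    labels = np.asarray(data.adulterant)
    groups = list(dict.fromkeys(labels.tolist()))  # stable order of appearance
    if not groups:
        raise ValueError("no adulterant labels present")
    cal_parts, pred_parts = [], []
    for g in groups:
        rows = np.flatnonzero(labels == g)
        sub = data.subset(rows)
        res = spxy_split(sub, fraction)
        cal_parts.append(rows[res.calibration_idx])
        pred_parts.append(rows[res.prediction_idx])
    return SplitResult(
        calibration_idx=np.sort(np.concatenate(cal_parts)),
        prediction_idx=np.sort(np.concatenate(pred_parts)),
    )
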