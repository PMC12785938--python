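"""Domain types, spectral CSV I/O, reflectance/absorbance conversion and
wavelength-range truncation.

The canonical on-disk format is a wide CSV: one row per sample with columns
``sample_id, adulterant, target, <wl1>, <wl2>, ...`` where wavelength column
headers are numeric nanometre values in strictly increasing order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "RawScan",
    "SpectraSet",
    "ADULTERANTS",
    "compute_reflectance",
    "reflectance_to_absorbance",
    "truncate_range",
    "read_spectra_csv",
    "write_spectra_csv",
]

#: Canonical adulterant labels used throughout the pipeline.
ADULTERANTS = ("corn_flour", "wheat_bran", "rice_bran", "stem_powder")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing grid of wavelengths in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be 1-D with at least 2 points")
        if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths_nm, other.wavelengths_nm)


@dataclass(frozen=True)
class RawScan:
    """One raw acquisition: sample, dark and white-reference detector counts."""

    grid: WavelengthGrid
    sample_signal: np.ndarray
    dark_signal: np.ndarray
    white_signal: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.grid)
        for name in ("sample_signal", "dark_signal", "white_signal"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (p,):
                raise ValueError(f"{name} must have length {p}, got shape {v.shape}")


@dataclass
class SpectraSet:
    """n samples x p wavelengths of absorbance with targets and labels.

    ``target`` is the mass fraction of the genuine powder, in [0, 1];
    ``adulterant`` is a categorical label per sample.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    target: np.ndarray
    adulterant: np.ndarray
    sample_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        A = np.asarray(self.absorbance, dtype=float)
        if A.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = A.shape
        if p != len(self.grid):
            raise ValueError(
                f"absorbance has {p} columns but grid has {len(self.grid)} wavelengths"
            )
        if not np.all(np.isfinite(A)):
            raise ValueError("absorbance contains non-finite values")
        y = np.asarray(self.target, dtype=float)
        lab = np.asarray(self.adulterant, dtype=object)
        if self.sample_id is None:
            sid = np.array([f"s{i:04d}" for i in range(n)], dtype=object)
        else:
            sid = np.asarray(self.sample_id, dtype=object)
        for name, v in (("target", y), ("adulterant", lab), ("sample_id", sid)):
            if v.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got shape {v.shape}")
        if np.any(y < 0) or np.any(y > 1):
            raise ValueError("targets must lie in [0, 1]")
        if len(set(sid.tolist())) != n:
            raise ValueError("sample_id values must be unique")
        self.absorbance = A
        self.target = y
        self.adulterant = lab
        self.sample_id = sid

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, rows: np.ndarray | list[int]) -> "SpectraSet":
        """Row subset preserving order of ``rows``."""
        rows = np.asarray(rows, dtype=int)
        return SpectraSet(
            grid=self.grid,
            absorbance=self.absorbance[rows],
            target=self.target[rows],
            adulterant=self.adulterant[rows],
            sample_id=self.sample_id[rows],
        )

    def select_columns(self, cols: np.ndarray | list[int]) -> "SpectraSet":
        """Wavelength-column subset (used by variable selection)."""
        cols = np.asarray(cols, dtype=int)
        return SpectraSet(
            grid=WavelengthGrid(self.grid.wavelengths_nm[cols]),
            absorbance=self.absorbance[:, cols],
            target=self.target,
            adulterant=self.adulterant,
            sample_id=self.sample_id,
        )

    def with_absorbance(self, A: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            grid=self.grid,
            absorbance=A,
            target=self.target,
            adulterant=self.adulterant,
            sample_id=self.sample_id,
        )


def compute_reflectance(scan: RawScan) -> np.ndarray:
    """Reflectance relative to the white reference.

    R = (S - D) / (W - D) elementwise over the grid.
    """
    denom = scan.white_signal - scan.dark_signal
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        wl = scan.grid.wavelengths_nm[bad[0]]
        raise ZeroDivisionError(
            f"white and dark signals coincide at {wl:g} nm (division by zero)"
        )
    return (scan.sample_signal - scan.dark_signal) / denom


def reflectance_to_absorbance(reflectance: np.ndarray) -> np.ndarray:
    """Absorbance A = log10(1/R); requires strictly positive reflectance."""
    r = np.asarray(reflectance, dtype=float)
    bad = np.flatnonzero(r <= 0)
    if bad.size:
        raise ValueError(
            f"reflectance must be positive; offending index {bad[0]} (value {r[bad[0]]:g})"
        )
    return np.log10(1.0 / r)


def truncate_range(data: SpectraSet, lo_nm: float, hi_nm: float) -> SpectraSet:
    """Retain wavelengths in the closed interval [lo_nm, hi_nm]."""
    if not lo_nm < hi_nm:
        if lo_nm != hi_nm:
            raise ValueError("lo_nm must not exceed hi_nm")
    wl = data.grid.wavelengths_nm
    keep = np.flatnonzero((wl >= lo_nm) & (wl <= hi_nm))
    if keep.size == 0:
        raise ValueError(f"no wavelengths in [{lo_nm:g}, {hi_nm:g}] nm")
    if keep.size == 1:
        # WavelengthGrid requires >= 2 points; keep a degenerate single-column
        # set by bypassing grid validation via a 2-point stub is worse than an
        # honest container -- return a SpectraSet-like with duplicated checks.
        return _single_column_set(data, int(keep[0]))
    return data.select_columns(keep)


def _single_column_set(data: SpectraSet, col: int) -> SpectraSet:
    """Degenerate one-wavelength set (grid invariant relaxed)."""
    out = SpectraSet.__new__(SpectraSet)
    grid = WavelengthGrid.__new__(WavelengthGrid)
    object.__setattr__(grid, "wavelengths_nm", data.grid.wavelengths_nm[[col]])
    out.grid = grid
    out.absorbance = data.absorbance[:, [col]]
    out.target = data.target
    out.adulterant = data.adulterant
    out.sample_id = data.sample_id
    return out


_META_COLS = ("sample_id", "adulterant", "target")


def write_spectra_csv(data: SpectraSet, path) -> None:
    """Write the wide-CSV canonical format (UTF-8, full float precision)."""
    df = pd.DataFrame(
        data.absorbance,
        columns=[repr(float(w)) for w in data.grid.wavelengths_nm],
    )
    df.insert(0, "target", data.target)
    df.insert(0, "adulterant", data.adulterant)
    df.insert(0, "sample_id", data.sample_id)
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> SpectraSet:
    """Read the wide-CSV canonical format, validating all invariants."""
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    wl_cols = [c for c in df.columns if c not in _META_COLS]
    if not wl_cols:
        raise ValueError("no wavelength columns found")
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as e:
        raise ValueError(f"non-numeric wavelength column header: {e}") from e
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength columns must be strictly increasing")
    y = df["target"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("targets outside [0, 1] in file")
    return SpectraSet(
        grid=WavelengthGrid(wl),
        absorbance=df[wl_cols].to_numpy(dtype=float),
        target=y,
        adulterant=df["adulterant"].to_numpy(dtype=object),
        sample_id=df["sample_id"].to_numpy(dtype=object),
    )
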