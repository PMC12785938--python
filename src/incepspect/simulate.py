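"""Synthetic adulterated-powder NIR spectra.

The forward model is linear (Beer-Lambert-like) mixing of Gaussian-band
endmember absorbance spectra, corrupted by multiplicative scatter (gain),
baseline offset and additive noise:

    A = g * (f * A_pure + (1 - f) * A_adulterant) + offset + eps

with g ~ N(1, gain_sd), offset ~ N(0, offset_sd), eps iid N(0, additive_sd).
All endmembers share absorption band centres near 1200 / 1420 / 1700 /
1900 / 2100 nm with component-specific amplitudes, so pure and adulterated
spectra overlap heavily but differ quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_core import ADULTERANTS, SpectraSet, WavelengthGrid

__all__ = [
    "ComponentSpectrum",
    "MixtureDesign",
    "NoiseModel",
    "BAND_CENTERS_NM",
    "default_grid",
    "make_default_endmembers",
    "simulate_spectrum",
    "simulate_dataset",
]

#: Shared absorption band centres (nm) of all default endmembers.
BAND_CENTERS_NM = (1200.0, 1420.0, 1700.0, 1900.0, 2100.0)

#: Default grid: 213 evenly spaced points spanning 1000-2400 nm.
DEFAULT_GRID_POINTS = 213
DEFAULT_GRID_SPAN = (1000.0, 2400.0)


def default_grid(n_points: int = DEFAULT_GRID_POINTS) -> WavelengthGrid:
    lo, hi = DEFAULT_GRID_SPAN
    return WavelengthGrid(np.linspace(lo, hi, n_points))


@dataclass(frozen=True)
class ComponentSpectrum:
    """Pure-component absorbance model: sum of Gaussian bands + baseline."""

    name: str
    bands: tuple  # of (center_nm, width_nm, amplitude)
    baseline: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = DEFAULT_GRID_SPAN
        for c, w, a in self.bands:
            if w <= 0:
                raise ValueError(f"band width must be > 0 (component {self.name})")
            if a < 0:
                raise ValueError(f"band amplitude must be >= 0 (component {self.name})")
            if not lo <= c <= hi:
                raise ValueError(
                    f"band centre {c:g} nm outside simulated span (component {self.name})"
                )

    def evaluate(self, grid: WavelengthGrid) -> np.ndarray:
        """Noiseless absorbance on ``grid``."""
        wl = grid.wavelengths_nm
        out = np.full(wl.shape, self.baseline, dtype=float)
        for c, w, a in self.bands:
            out += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
        return out


@dataclass(frozen=True)
class MixtureDesign:
    """Which mixtures to simulate: fraction levels x adulterants x replicates."""

    levels: tuple = tuple(np.round(np.arange(0, 21) * 0.05, 2))
    adulterants: tuple = ADULTERANTS
    replicates_per_level: int = 5

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if np.any(lv < 0) or np.any(lv > 1):
            raise ValueError("levels must lie in [0, 1]")
        if np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be strictly increasing")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.levels) * len(self.adulterants) * self.replicates_per_level


@dataclass(frozen=True)
class NoiseModel:
    """Scatter/noise parameters of the forward model (all in absorbance units
    except the unitless multiplicative gain spread)."""

    additive_sd: float = 0.005
    gain_sd: float = 0.03
    offset_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "gain_sd", "offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseModel":
        return cls(additive_sd=0.0, gain_sd=0.0, offset_sd=0.0, seed=seed)


def make_default_endmembers() -> list[ComponentSpectrum]:
    """Pure powder plus the four adulterants.

    All five components share the default band centres, so their noiseless
    spectra have pairwise cosine similarity above 0.9 while differing in band
    amplitude -- a quantitative rather than positional contrast.
    """
    widths = (45.0, 35.0, 55.0, 60.0, 70.0)

    def comp(name: str, amps, baseline: float) -> ComponentSpectrum:
        bands = tuple(
            (c, w, a) for c, w, a in zip(BAND_CENTERS_NM, widths, amps)
        )
        return ComponentSpectrum(name=name, bands=bands, baseline=baseline)

    return [
        comp("zanthoxylum", (0.30, 0.55, 0.40, 0.70, 0.50), 0.35),
        comp("corn_flour", (0.55, 0.30, 0.15, 0.45, 0.80), 0.25),
        comp("wheat_bran", (0.41, 0.44, 0.40, 0.55, 0.38), 0.31),
        comp("rice_bran", (0.45, 0.40, 0.52, 0.42, 0.44), 0.29),
        comp("stem_powder", (0.23, 0.64, 0.30, 0.83, 0.50), 0.39),
    ]


def _endmember_map() -> dict[str, ComponentSpectrum]:
    return {c.name: c for c in make_default_endmembers()}


def simulate_spectrum(
    fraction: float,
    adulterant: ComponentSpectrum,
    pure: ComponentSpectrum,
    grid: WavelengthGrid,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One mixture spectrum at a given mass fraction of the pure powder."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    clean = fraction * pure.evaluate(grid) + (1.0 - fraction) * adulterant.evaluate(grid)
    g = rng.normal(1.0, noise.gain_sd)
    offset = rng.normal(0.0, noise.offset_sd)
    eps = rng.normal(0.0, noise.additive_sd, size=len(grid))
    return g * clean + offset + eps


def simulate_dataset(
    design: MixtureDesign = MixtureDesign(),
    noise: NoiseModel = NoiseModel(),
    grid: WavelengthGrid | None = None,
) -> SpectraSet:
    """One sample per (adulterant, level, replicate); defaults give n = 420.

    Targets equal the designed fractions exactly; everything is reproducible
    from ``noise.seed``.
    """
    if grid is None:
        grid = default_grid()
    endmembers = _endmember_map()
    pure = endmembers["zanthoxylum"]
    rng = np.random.default_rng(noise.seed)

    rows, targets, labels, sids = [], [], [], []
    i = 0
    for name in design.adulterants:
        if name not in endmembers:
            raise KeyError(f"unknown adulterant '{name}'")
        adult = endmembers[name]
        for level in design.levels:
            for rep in range(design.replicates_per_level):
                rows.append(
                    simulate_spectrum(float(level), adult, pure, grid, noise, rng)
                )
                targets.append(float(level))
                labels.append(name)
                sids.append(f"{name}_l{round(level * 100):03d}_r{rep}")
                i += 1
    return SpectraSet(
        grid=grid,
        absorbance=np.array(rows),
        target=np.array(targets),
        adulterant=np.array(labels, dtype=object),
        sample_id=np.array(sids, dtype=object),
    )
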