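"""Isotopic fine-structure simulation and resolution-limited profile rendering.

Patterns are built by per-element convolution with pruning: the single-atom
distribution of each element is raised to its atom count by binary powering,
partial patterns are merged by convolution, and after every step entries are
binned at a configurable mass tolerance (1e-4 Da default) and entries below
an abundance floor are dropped. For the <= 8 kDa metalloprotein complexes
this package targets, the result is indistinguishable from exact enumeration
at any realistic instrument resolution; tests check exact agreement with a
brute-force multinomial oracle on small molecules.
"""

from __future__ import annotations

import functools
from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import PROTON_MASS, ElementalComposition, isotope_table

__all__ = [
    "IsotopePattern",
    "Spectrum",
    "isotope_pattern",
    "to_mz",
    "render_profile",
    "render_on_grid",
]

DEFAULT_PRUNE = 1e-10
DEFAULT_BIN_WIDTH = 1e-4
#: Synapt-class default resolving power (m / FWHM), configurable everywhere.
DEFAULT_RESOLVING_POWER = 20_000.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True, eq=False)
class IsotopePattern:
    """Stick isotope pattern in neutral-mass or m/z space.

    Entries are sorted ascending and abundances are normalized to sum to 1.
    """

    positions: np.ndarray
    abundances: np.ndarray
    domain: str = "neutral-mass"  # or "m/z"
    charge: int = 0
    #: total abundance surviving pruning, before renormalization
    retained: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ab = np.asarray(self.abundances, dtype=float)
        if pos.ndim != 1 or pos.shape != ab.shape or pos.size == 0:
            raise ValueError("pattern needs matching, non-empty 1-d arrays")
        if np.any(ab <= 0):
            raise ValueError("abundances must be strictly positive")
        if self.domain not in ("neutral-mass", "m/z"):
            raise ValueError(f"unknown domain {self.domain!r}")
        order = np.argsort(pos, kind="stable")
        pos, ab = pos[order], ab[order]
        ab = ab / ab.sum()
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "abundances", ab)
        pos.setflags(write=False)
        ab.setflags(write=False)

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def base_position(self) -> float:
        """Position of the most abundant stick."""
        return float(self.positions[np.argmax(self.abundances)])


@dataclass
class Spectrum:
    """Profile (or centroided) spectrum on an ascending m/z axis."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""
    charge: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be matching 1-d arrays")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


def _bin_sticks(
    masses: np.ndarray, abundances: np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge sticks closer than ``bin_width`` (abundance-weighted centroid)."""
    keys = np.round(masses / bin_width).astype(np.int64)
    order = np.argsort(keys, kind="stable")
    keys, masses, abundances = keys[order], masses[order], abundances[order]
    boundaries = np.flatnonzero(np.diff(keys)) + 1
    groups = np.concatenate(([0], boundaries))
    ab = np.add.reduceat(abundances, groups)
    weighted = np.add.reduceat(masses * abundances, groups)
    return weighted / ab, ab


def _convolve(
    a: tuple[np.ndarray, np.ndarray],
    b: tuple[np.ndarray, np.ndarray],
    prune: float,
    bin_width: float,
) -> tuple[np.ndarray, np.ndarray]:
    masses = (a[0][:, None] + b[0][None, :]).ravel()
    ab = (a[1][:, None] * b[1][None, :]).ravel()
    masses, ab = _bin_sticks(masses, ab, bin_width)
    if prune > 0:
        keep = ab >= prune
        if not np.all(keep):
            masses, ab = masses[keep], ab[keep]
    return masses, ab


@functools.lru_cache(maxsize=512)
def _element_pattern(
    element: str, count: int, prune: float, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pattern of ``count`` atoms of one element, by binary powering."""
    table = isotope_table()
    if element not in table:
        raise KeyError(f"element {element!r} is not in the bundled isotope table")
    single = table[element]
    result: tuple[np.ndarray, np.ndarray] | None = None
    power = (np.array(single[0], float), np.array(single[1], float))
    n = count
    while n:
        if n & 1:
            result = power if result is None else _convolve(result, power, prune, bin_width)
        n >>= 1
        if n:
            power = _convolve(power, power, prune, bin_width)
    assert result is not None
    return result


def isotope_pattern(
    composition: Mapping[str, int],
    prune: float = DEFAULT_PRUNE,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> IsotopePattern:
    """Isotopologue stick pattern of a neutral composition.

    ``prune`` is the per-step abundance floor: after each convolution, sticks
    below it are discarded, so the retained total abundance is at least
    ``1 - prune * k`` where ``k`` is the number of sticks pruned over all
    steps (>= 0.999 in practice at the default). The result is renormalized.

    Parameters
    ----------
    composition : element -> count map (neutral molecule).
    prune : abundance floor in [0, 1).
    bin_width : mass tolerance (Da) for merging quasi-degenerate sticks.
    """
    if not 0 <= prune < 1:
        raise ValueError("prune must be in [0, 1)")
    comp = ElementalComposition(composition)
    if len(comp) == 0:
        return IsotopePattern(np.array([0.0]), np.array([1.0]))
    result: tuple[np.ndarray, np.ndarray] | None = None
    for element, count in comp.items():
        part = _element_pattern(element, count, prune, bin_width)
        result = part if result is None else _convolve(result, part, prune, bin_width)
    assert result is not None
    return IsotopePattern(result[0], result[1], retained=float(result[1].sum()))


def to_mz(pattern: IsotopePattern, z: int) -> IsotopePattern:
    """Protonated m/z pattern of a neutral-mass pattern: (m + z*mp)/z."""
    if z <= 0:
        raise ValueError("charge must be a positive integer")
    if pattern.domain != "neutral-mass":
        raise ValueError("pattern is already in the m/z domain")
    return replace(
        pattern,
        positions=(pattern.positions + z * PROTON_MASS) / z,
        domain="m/z",
        charge=int(z),
    )


def _aggregate_for_render(
    pattern: IsotopePattern, resolving_power: float
) -> tuple[np.ndarray, np.ndarray]:
    # fine structure far below the peak width is invisible; merging it first
    # makes rendering ~50x cheaper for 7 kDa envelopes
    fwhm = pattern.base_position / resolving_power
    return _bin_sticks(pattern.positions, pattern.abundances, fwhm / 10.0)


def render_on_grid(
    pattern: IsotopePattern,
    grid: np.ndarray,
    resolving_power: float = DEFAULT_RESOLVING_POWER,
    shift: float = 0.0,
) -> np.ndarray:
    """Gaussian-profile intensities of an m/z pattern on an existing grid.

    Peak areas are proportional to stick abundances; FWHM = center /
    resolving_power. ``shift`` displaces the whole pattern (Th), which the
    fitting layer uses to absorb small calibration offsets.
    """
    if pattern.domain != "m/z":
        raise ValueError("profile rendering expects an m/z-domain pattern")
    if resolving_power <= 0:
        raise ValueError("resolving power must be positive")
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    centers, areas = _aggregate_for_render(pattern, resolving_power)
    step = grid[1] - grid[0] if grid.size > 1 else 1.0
    for center, area in zip(centers + shift, areas):
        sigma = (center / resolving_power) * _FWHM_TO_SIGMA
        lo = np.searchsorted(grid, center - 6 * sigma)
        hi = np.searchsorted(grid, center + 6 * sigma)
        if hi > lo:
            window = grid[lo:hi]
            out[lo:hi] += (
                area / (sigma * np.sqrt(2 * np.pi))
                * np.exp(-0.5 * ((window - center) / sigma) ** 2)
            )
    return out


def render_profile(
    pattern: IsotopePattern,
    resolving_power: float = DEFAULT_RESOLVING_POWER,
    grid_step: float | None = None,
    pad_fwhm: float = 5.0,
) -> Spectrum:
    """Render an m/z stick pattern as a Gaussian profile spectrum.

    The grid spans the pattern +/- ``pad_fwhm`` FWHM; the default step is
    FWHM/8 at the base peak. Intensities are in area units (integral of each
    peak equals its stick abundance); display layers may renormalize to
    max = 1.
    """
    if pattern.domain != "m/z":
        raise ValueError("profile rendering expects an m/z-domain pattern")
    if resolving_power <= 0:
        raise ValueError("resolving power must be positive")
    fwhm = pattern.base_position / resolving_power
    if grid_step is None:
        grid_step = fwhm / 8.0
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    lo = pattern.positions[0] - pad_fwhm * fwhm
    hi = pattern.positions[-1] + pad_fwhm * fwhm
    grid = np.arange(lo, hi + grid_step, grid_step)
    intensity = render_on_grid(pattern, grid, resolving_power)
    return Spectrum(grid, intensity, charge=pattern.charge or None)
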