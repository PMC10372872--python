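"""Synthetic fixtures emulating native IM-MS data of metal-MT3 complexes.

Every generator is a pure function of its parameters and a seed, producing:
isotopically resolved charge-state envelopes of overlapping Cu/Zn/disulfide
species, two-conformer arrival-time distributions whose populations shift
logistically with collision energy, sigmoidal survival-yield curves, and
fragment peak lists with decoys kept away from every theoretical ion. The
defaults mirror the acquisition regime of a Synapt-class instrument on a
7 kDa metalloprotein (resolving power 20,000, 1% Gaussian intensity noise,
trap CE steps within 0-60 V).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import MetalComplexSpecies
from .isotopes import (
    DEFAULT_RESOLVING_POWER,
    Spectrum,
    render_on_grid,
    to_mz,
)
from .mobility import ArrivalTimeDistribution, CCSCalibration
from .stoichiometry import species_pattern
from .survival import SurvivalYieldCurve, sigmoid

__all__ = [
    "SyntheticSpec",
    "synth_spectrum",
    "synth_ciu",
    "synth_sy",
    "synth_fragment_peaks",
]


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic profile spectrum of one or more species.

    ``species`` pairs each complex with its fractional abundance (must sum
    to 1); every charge in ``charges`` receives equal weight. Noise is
    Gaussian with sigma relative to the maximum intensity (Poisson counting
    noise optional); a seed is mandatory whenever any noise is requested.
    """

    species: list[tuple[MetalComplexSpecies, float]]
    charges: list[int] = field(default_factory=lambda: [5])
    resolving_power: float = DEFAULT_RESOLVING_POWER
    noise_sigma: float = 0.0
    poisson: bool = False
    seed: int | None = None
    grid_step: float | None = None
    prune: float = 1e-8

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species is required")
        fractions = [f for _, f in self.species]
        if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("species abundances must be non-negative and sum to 1")
        if not self.charges or any(z < 1 for z in self.charges):
            raise ValueError("charges must be positive integers")
        if (self.noise_sigma > 0 or self.poisson) and self.seed is None:
            raise ValueError("a seed is mandatory for any noisy output")


def synth_spectrum(cfg: SyntheticSpec) -> Spectrum:
    """Render all species at all charges on one grid, plus optional noise."""
    patterns = []
    for sp, fraction in cfg.species:
        for z in cfg.charges:
            patterns.append((to_mz(species_pattern(sp, cfg.prune), z), fraction / len(cfg.charges)))
    lo = min(p.positions[0] for p, _ in patterns)
    hi = max(p.positions[-1] for p, _ in patterns)
    fwhm = patterns[0][0].base_position / cfg.resolving_power
    step = cfg.grid_step if cfg.grid_step is not None else fwhm / 8.0
    grid = np.arange(lo - 5 * fwhm, hi + 5 * fwhm + step, step)
    intensity = np.zeros_like(grid)
    for pattern, weight in patterns:
        intensity += weight * render_on_grid(pattern, grid, cfg.resolving_power)
    rng = np.random.default_rng(cfg.seed) if cfg.seed is not None else None
    if cfg.poisson:
        scale = 1e4 / intensity.max()  # ~1e4 counts at the base peak
        intensity = rng.poisson(intensity * scale).astype(float) / scale
    if cfg.noise_sigma > 0:
        intensity = intensity + rng.normal(
            0.0, cfg.noise_sigma * intensity.max(), intensity.shape
        )
        intensity = np.clip(intensity, 0.0, None)
    label = " + ".join(sp.describe() for sp, _ in cfg.species)
    return Spectrum(grid, intensity, label=label)


def synth_ciu(
    midpoint_ce: float,
    compact_ccs: float,
    extended_ccs: float,
    cal: CCSCalibration,
    ion_mass: float,
    charge: int,
    ccs_width: float = 40.0,
    ce_grid: np.ndarray | None = None,
    logistic_width: float = 4.0,
    n_points: int = 300,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    label: str = "synthetic ion",
) -> dict[float, ArrivalTimeDistribution]:
    """Two-conformer CIU fixture: per-CE ATDs with a logistic unfolding step.

    At each trap CE the extended-conformer fraction is
    logistic((CE - midpoint_ce)/logistic_width); compact and extended
    populations are Gaussians centred at the arrival times that the inverse
    calibration assigns to ``compact_ccs`` and ``extended_ccs``.
    """
    if compact_ccs >= extended_ccs:
        raise ValueError("compact CCS must be smaller than extended CCS")
    if noise_sigma > 0 and seed is None:
        raise ValueError("a seed is mandatory for any noisy output")
    if ce_grid is None:
        ce_grid = np.arange(0.0, 62.0, 2.0)
    rng = np.random.default_rng(seed) if seed is not None else None
    centers = cal.inverse(
        np.array([compact_ccs, extended_ccs]), ion_mass, charge
    )
    sigmas = np.array(
        [
            (
                cal.inverse(c + ccs_width / 2, ion_mass, charge)
                - cal.inverse(c - ccs_width / 2, ion_mass, charge)
            )
            / (2 * np.sqrt(2 * np.log(2)))
            for c in (compact_ccs, extended_ccs)
        ]
    )
    t_lo = centers[0] - 6 * sigmas[0]
    t_hi = centers[1] + 6 * sigmas[1]
    times = np.linspace(max(t_lo, 1e-3), t_hi, n_points)
    out: dict[float, ArrivalTimeDistribution] = {}
    for ce in np.asarray(ce_grid, float):
        f_ext = 1.0 / (1.0 + np.exp(-(ce - midpoint_ce) / logistic_width))
        intensity = (1.0 - f_ext) * np.exp(
            -0.5 * ((times - centers[0]) / sigmas[0]) ** 2
        ) / sigmas[0] + f_ext * np.exp(
            -0.5 * ((times - centers[1]) / sigmas[1]) ** 2
        ) / sigmas[1]
        if noise_sigma > 0:
            intensity = np.clip(
                intensity + rng.normal(0, noise_sigma * intensity.max(), times.shape),
                0.0,
                None,
            )
        out[float(ce)] = ArrivalTimeDistribution(
            times=times,
            intensity=intensity,
            label=label,
            charge=charge,
            mass=ion_mass,
            tw_set=cal.tw_set,
        )
    return out


def synth_sy(
    e50: float,
    width: float,
    grid: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    top: float = 1.0,
    bottom: float = 0.0,
    label: str = "",
) -> SurvivalYieldCurve:
    """Sigmoid survival-yield curve sampled on an E_com grid, with noise."""
    if width <= 0:
        raise ValueError("sigmoid width must be positive")
    if noise_sigma > 0 and seed is None:
        raise ValueError("a seed is mandatory for any noisy output")
    grid = np.asarray(grid, float)
    sy = sigmoid(grid, e50, width, top, bottom)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        sy = sy + rng.normal(0.0, noise_sigma, sy.shape)
    return SurvivalYieldCurve(e_com=grid, sy=np.clip(sy, 0.0, 1.0), label=label)


def synth_fragment_peaks(
    planted_mz: np.ndarray,
    all_theoretical_mz: np.ndarray,
    ppm_jitter: float = 0.0,
    n_decoys: int = 0,
    seed: int | None = None,
    decoy_min_ppm: float = 50.0,
    mz_range: tuple[float, float] | None = None,
    max_tries: int = 10_000,
) -> list[tuple[float, float]]:
    """Peak list with planted fragments plus decoys far from any theoretical ion.

    Planted peaks sit at their theoretical m/z displaced by a uniform jitter
    within +/- ``ppm_jitter``; every decoy is rejection-sampled until it is
    at least ``decoy_min_ppm`` from every theoretical m/z supplied.
    """
    planted_mz = np.asarray(planted_mz, float)
    all_theoretical_mz = np.sort(np.asarray(all_theoretical_mz, float))
    if (ppm_jitter > 0 or n_decoys > 0) and seed is None:
        raise ValueError("a seed is mandatory for any randomized output")
    rng = np.random.default_rng(seed) if seed is not None else None
    peaks: list[tuple[float, float]] = []
    for mz in planted_mz:
        jitter = rng.uniform(-ppm_jitter, ppm_jitter) if ppm_jitter > 0 else 0.0
        peaks.append((mz * (1.0 + jitter * 1e-6), float(rng.uniform(0.3, 1.0)) if rng is not None else 1.0))
    if mz_range is None:
        lo = float(all_theoretical_mz[0]) * 0.95
        hi = float(all_theoretical_mz[-1]) * 1.05
    else:
        lo, hi = mz_range
    placed = 0
    tries = 0
    while placed < n_decoys:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place decoy {placed + 1}/{n_decoys}: theoretical ions "
                "too dense for the requested exclusion distance"
            )
        tries += 1
        mz = rng.uniform(lo, hi)
        idx = np.searchsorted(all_theoretical_mz, mz)
        neighbors = all_theoretical_mz[max(idx - 1, 0): idx + 1]
        if np.all(np.abs(mz - neighbors) / neighbors * 1e6 >= decoy_min_ppm):
            peaks.append((mz, float(rng.uniform(0.05, 0.5))))
            placed += 1
    peaks.sort()
    return peaks
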