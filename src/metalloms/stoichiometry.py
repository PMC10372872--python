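"""Metal/disulfide stoichiometry assignment by isotopic-envelope fitting.

Cu(I) and Zn(II) differ by only ~1.8 Da in average mass and their isotope
patterns overlap, so a Cu_xZn_y(SS_s) assignment cannot be read off a single
centroid. Instead, candidate species are enumerated on a (n_cu, n_zn, n_ss)
grid, their theoretical isotopic envelopes are rendered at instrument
resolution, and each is scored against the observed profile; the best-scoring
candidate wins, with parsimony tie-breaks. A non-negative least-squares
mixture fit resolves transiently overlapping species.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .chem import (
    MetalComplexSpecies,
    ProteinSequence,
    average_mass,
    species_composition,
)
from .isotopes import (
    DEFAULT_RESOLVING_POWER,
    IsotopePattern,
    Spectrum,
    isotope_pattern,
    render_on_grid,
    to_mz,
)

__all__ = [
    "CandidateGrid",
    "FitResult",
    "MixtureResult",
    "AssignmentRanking",
    "enumerate_candidates",
    "species_pattern",
    "score_fit",
    "assign_species",
    "fit_mixture",
    "infer_charge",
]

#: Bound on the global m/z shift absorbed during scoring (Th). Kept well
#: below the ~0.2 Th isotopologue spacing at z=5 so the optimizer cannot hop
#: the fit onto the neighbouring isotope peak.
DEFAULT_SHIFT_BOUND = 0.05


@dataclass(frozen=True)
class CandidateGrid:
    """Inclusive ranges for the candidate (n_cu, n_zn, n_ss) enumeration.

    ``mass_window`` optionally restricts candidates to those whose neutral
    average mass lies within ``(target, +/- half_width)`` Da.
    """

    cu_range: tuple[int, int] = (0, 8)
    zn_range: tuple[int, int] = (0, 7)
    ss_range: tuple[int, int] = (0, 2)
    mass_window: tuple[float, float] | None = None
    enforce_thiol_budget: bool = True

    def __post_init__(self) -> None:
        for name in ("cu_range", "zn_range", "ss_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi, got {(lo, hi)}")
        if self.mass_window is not None and self.mass_window[1] <= 0:
            raise ValueError("mass window half-width must be positive")


@dataclass(frozen=True)
class FitResult:
    """One candidate's fit against an observed envelope."""

    species: MetalComplexSpecies | None
    charge: int
    score: float
    scale: float
    mz_shift: float
    residual: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.score <= 1 + 1e-9:
            raise ValueError("score must lie in [0, 1]")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")


@dataclass(frozen=True, eq=False)
class MixtureResult:
    """Non-negative abundances of a candidate basis fit to one spectrum."""

    species: tuple[MetalComplexSpecies, ...]
    abundances: np.ndarray  # fractions, sum to 1 when any signal is explained
    scales: np.ndarray  # raw NNLS coefficients
    residual: float


@dataclass(frozen=True)
class AssignmentRanking:
    """Ranked fit results; ``margin`` is the top-two score separation."""

    results: tuple[FitResult, ...]
    margin: float

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, index):
        return self.results[index]

    def __len__(self) -> int:
        return len(self.results)

    @property
    def best(self) -> FitResult:
        return self.results[0]


def enumerate_candidates(
    grid: CandidateGrid, base: ProteinSequence
) -> list[MetalComplexSpecies]:
    """All admissible species on the grid, lexicographic in (n_cu, n_zn, n_ss)."""
    out: list[MetalComplexSpecies] = []
    for n_cu in range(grid.cu_range[0], grid.cu_range[1] + 1):
        for n_zn in range(grid.zn_range[0], grid.zn_range[1] + 1):
            for n_ss in range(grid.ss_range[0], grid.ss_range[1] + 1):
                try:
                    sp = MetalComplexSpecies(
                        base,
                        n_cu,
                        n_zn,
                        n_ss,
                        enforce_thiol_budget=grid.enforce_thiol_budget,
                    )
                except ValueError:
                    continue
                if grid.mass_window is not None:
                    target, half = grid.mass_window
                    if abs(average_mass(species_composition(sp)) - target) > half:
                        continue
                out.append(sp)
    if not out:
        warnings.warn("candidate grid produced no admissible species", stacklevel=2)
    return out


@functools.lru_cache(maxsize=2048)
def _cached_pattern(
    base_residues: str, n_cu: int, n_zn: int, n_ss: int, prune: float
) -> IsotopePattern:
    sp = MetalComplexSpecies(
        ProteinSequence(base_residues), n_cu, n_zn, n_ss, enforce_thiol_budget=False
    )
    return isotope_pattern(species_composition(sp), prune=prune)


def species_pattern(sp: MetalComplexSpecies, prune: float = 1e-8) -> IsotopePattern:
    """Neutral-mass isotope pattern of a species (memoized across calls)."""
    return _cached_pattern(sp.base.residues, sp.n_cu, sp.n_zn, sp.n_ss, prune)


def _envelope_region(
    pattern_mz: IsotopePattern, observed: Spectrum, shift_bound: float
) -> slice:
    pad = 3 * pattern_mz.base_position / DEFAULT_RESOLVING_POWER + shift_bound
    lo = np.searchsorted(observed.mz, pattern_mz.positions[0] - pad)
    hi = np.searchsorted(observed.mz, pattern_mz.positions[-1] + pad)
    if hi - lo < 3:
        raise ValueError(
            "observed spectrum does not cover the theoretical envelope "
            f"({pattern_mz.positions[0]:.2f}-{pattern_mz.positions[-1]:.2f} Th)"
        )
    return slice(lo, hi)


def score_fit(
    theoretical: IsotopePattern,
    observed: Spectrum,
    z: int,
    resolving_power: float = DEFAULT_RESOLVING_POWER,
    shift_bound: float = DEFAULT_SHIFT_BOUND,
    optimize_shift: bool = True,
    species: MetalComplexSpecies | None = None,
) -> FitResult:
    """Cosine-similarity fit of one theoretical envelope to a spectrum.

    The theoretical pattern (m/z domain, charge ``z``) is rendered at
    instrument resolution on the observed grid, a global m/z shift within
    ``+/- shift_bound`` is optimized to absorb calibration offset, and the
    score is the normalized dot product on the shared grid (1 iff the two
    profiles are proportional). ``scale`` is the least-squares intensity
    factor and ``residual`` the RMS misfit at that scale.
    """
    if theoretical.domain != "m/z":
        raise ValueError("theoretical pattern must be in the m/z domain")
    if theoretical.charge not in (0, z):
        raise ValueError(
            f"pattern charge {theoretical.charge} does not match requested z={z}"
        )
    region = _envelope_region(theoretical, observed, shift_bound)
    grid = observed.mz[region]
    obs = observed.intensity[region]
    obs_norm = float(np.linalg.norm(obs))
    if obs_norm == 0:
        raise ValueError("observed spectrum has no signal over the envelope region")

    def cosine(shift: float) -> tuple[float, np.ndarray]:
        theo = render_on_grid(theoretical, grid, resolving_power, shift=shift)
        norm = float(np.linalg.norm(theo))
        if norm == 0:
            return 0.0, theo
        return float(np.dot(theo, obs) / (norm * obs_norm)), theo

    best_shift = 0.0
    if optimize_shift and shift_bound > 0:
        res = optimize.minimize_scalar(
            lambda s: -cosine(s)[0],
            bounds=(-shift_bound, shift_bound),
            method="bounded",
            options={"xatol": 1e-4},
        )
        # keep zero shift unless the optimizer genuinely improves the score
        if -res.fun > cosine(0.0)[0]:
            best_shift = float(res.x)
    score, theo = cosine(best_shift)
    tt = float(np.dot(theo, theo))
    scale = float(np.dot(theo, obs) / tt) if tt > 0 else 0.0
    scale = max(scale, 0.0)
    residual = float(np.sqrt(np.mean((obs - scale * theo) ** 2)))
    return FitResult(
        species=species,
        charge=z,
        score=min(max(score, 0.0), 1.0),
        scale=scale,
        mz_shift=best_shift,
        residual=residual,
    )


def _parsimony_key(result: FitResult):
    sp = result.species
    metals = (sp.n_cu + sp.n_zn) if sp is not None else 0
    n_ss = sp.n_ss if sp is not None else 0
    return (-result.score, metals, n_ss)


def assign_species(
    observed: Spectrum,
    grid: CandidateGrid,
    base: ProteinSequence,
    z: int | None = None,
    resolving_power: float = DEFAULT_RESOLVING_POWER,
    shift_bound: float = DEFAULT_SHIFT_BOUND,
    prune: float = 1e-8,
    refine_top: int = 10,
) -> AssignmentRanking:
    """Rank every candidate species against an observed charge-state envelope.

    All candidates are scored at zero m/z shift; the bounded shift is then
    refined for the ``refine_top`` best, which is where it can matter for the
    ranking. Ties are broken toward chemically simpler species (fewer metals,
    then fewer disulfides). The charge is inferred from the isotopologue
    spacing when not supplied.
    """
    if z is None:
        z = infer_charge(observed)
    candidates = enumerate_candidates(grid, base)
    if not candidates:
        return AssignmentRanking(results=(), margin=0.0)
    results = []
    for sp in candidates:
        pattern = to_mz(species_pattern(sp, prune=prune), z)
        try:
            fit = score_fit(
                pattern,
                observed,
                z,
                resolving_power=resolving_power,
                shift_bound=shift_bound,
                optimize_shift=False,
                species=sp,
            )
        except ValueError:
            continue  # envelope entirely outside the recorded window
        results.append(fit)
    if not results:
        raise ValueError("no candidate envelope overlaps the observed spectrum")
    results.sort(key=_parsimony_key)
    refined = []
    for fit in results[: max(refine_top, 0)]:
        pattern = to_mz(species_pattern(fit.species, prune=prune), z)
        refined.append(
            score_fit(
                pattern,
                observed,
                z,
                resolving_power=resolving_power,
                shift_bound=shift_bound,
                optimize_shift=True,
                species=fit.species,
            )
        )
    results = refined + results[max(refine_top, 0):]
    results.sort(key=_parsimony_key)
    margin = results[0].score - results[1].score if len(results) > 1 else results[0].score
    return AssignmentRanking(results=tuple(results), margin=margin)


def fit_mixture(
    observed: Spectrum,
    candidates: list[MetalComplexSpecies],
    z: int,
    resolving_power: float = DEFAULT_RESOLVING_POWER,
    prune: float = 1e-8,
) -> MixtureResult:
    """Non-negative least-squares abundances of overlapping species.

    Each candidate envelope is rendered (unit stick-abundance, i.e. unit
    area) on the observed grid; NNLS coefficients are therefore proportional
    to the species' envelope areas, and ``abundances`` are those coefficients
    normalized to fractions.
    """
    if not candidates:
        raise ValueError("mixture fit needs at least one candidate")
    patterns = [to_mz(species_pattern(sp, prune=prune), z) for sp in candidates]
    lo = min(p.positions[0] for p in patterns)
    hi = max(p.positions[-1] for p in patterns)
    pad = 3 * patterns[0].base_position / resolving_power
    sel = slice(
        np.searchsorted(observed.mz, lo - pad),
        np.searchsorted(observed.mz, hi + pad),
    )
    grid = observed.mz[sel]
    obs = observed.intensity[sel]
    if grid.size < len(candidates) or not np.any(obs > 0):
        raise ValueError("observed spectrum does not cover the candidate envelopes")
    basis = np.column_stack(
        [render_on_grid(p, grid, resolving_power) for p in patterns]
    )
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        raise ValueError("candidate basis is singular (indistinguishable envelopes)")
    scales, rnorm = optimize.nnls(basis, obs)
    total = scales.sum()
    fractions = scales / total if total > 0 else scales
    return MixtureResult(
        species=tuple(candidates),
        abundances=fractions,
        scales=scales,
        residual=float(rnorm / np.sqrt(grid.size)),
    )


def infer_charge(observed: Spectrum, max_charge: int = 30) -> int:
    """Charge from isotopologue spacing: nearest integer of 1 / median spacing."""
    peaks, props = signal.find_peaks(
        observed.intensity, prominence=0.05 * observed.intensity.max()
    )
    if peaks.size < 2:
        raise ValueError("cannot infer charge: fewer than two isotopologue peaks")
    spacings = np.diff(observed.mz[peaks])
    spacing = float(np.median(spacings))
    z = int(round(1.0 / spacing))
    if not 1 <= z <= max_charge:
        raise ValueError(f"inferred charge {z} outside [1, {max_charge}]")
    return z
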