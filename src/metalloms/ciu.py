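"""Collision-induced unfolding fingerprints and conformer populations.

A CIU experiment records the arrival-time distribution of a mass-selected
ion at stepwise-increasing trap collision energies (CE). Each ATD is mapped
to CCS, resampled onto a common grid, and column-normalized (max = 1 per CE,
the standard CIU-fingerprint convention), giving a CE x CCS intensity map.
Compact/extended conformer populations are quantified by integrating the
CCS distribution on either side of a boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .mobility import ArrivalTimeDistribution, CCSCalibration, CCSDistribution, atd_to_ccs

__all__ = [
    "CIUFingerprint",
    "build_fingerprint",
    "conformer_ratio",
    "default_boundary",
    "extended_fraction_curve",
]


@dataclass(eq=False)
class CIUFingerprint:
    """CE x CCS intensity matrix, column-normalized per collision energy."""

    ce_axis: np.ndarray  # trap collision energies, V, ascending
    ccs_axis: np.ndarray  # A^2, ascending
    matrix: np.ndarray  # shape (len(ccs_axis), len(ce_axis))
    label: str = ""

    def __post_init__(self) -> None:
        self.ce_axis = np.asarray(self.ce_axis, float)
        self.ccs_axis = np.asarray(self.ccs_axis, float)
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (self.ccs_axis.size, self.ce_axis.size):
            raise ValueError("matrix shape must be (n_ccs, n_ce)")
        for name, axis in (("ce_axis", self.ce_axis), ("ccs_axis", self.ccs_axis)):
            if np.any(np.diff(axis) <= 0):
                raise ValueError(f"{name} must be strictly ascending")

    def column(self, index: int) -> CCSDistribution:
        return CCSDistribution(
            ccs=self.ccs_axis,
            intensity=self.matrix[:, index],
            label=f"{self.label} CE={self.ce_axis[index]:g} V",
        )


def build_fingerprint(
    atds: dict[float, ArrivalTimeDistribution],
    cal: CCSCalibration,
    n_grid: int = 400,
    label: str = "",
) -> CIUFingerprint:
    """Assemble a CIU fingerprint from per-CE arrival-time distributions.

    All ATDs must belong to the same quadrupole-selected ion (same label,
    charge and mass); at least two collision energies are required.
    """
    if len(atds) < 2:
        raise ValueError("a CIU fingerprint needs at least two collision energies")
    ces = sorted(atds)
    first = atds[ces[0]]
    for ce in ces[1:]:
        a = atds[ce]
        if (a.label, a.charge, a.mass) != (first.label, first.charge, first.mass):
            raise ValueError(
                f"inconsistent ion identity at CE={ce:g} V: "
                f"{(a.label, a.charge, a.mass)} vs {(first.label, first.charge, first.mass)}"
            )
    ccsds = {ce: atd_to_ccs(atds[ce], cal) for ce in ces}
    lo = min(d.ccs[0] for d in ccsds.values())
    hi = max(d.ccs[-1] for d in ccsds.values())
    grid = np.linspace(lo, hi, n_grid)
    matrix = np.zeros((n_grid, len(ces)))
    for j, ce in enumerate(ces):
        d = ccsds[ce]
        col = np.interp(grid, d.ccs, d.intensity, left=0.0, right=0.0)
        peak = col.max()
        matrix[:, j] = col / peak if peak > 0 else col
    return CIUFingerprint(
        ce_axis=np.asarray(ces, float),
        ccs_axis=grid,
        matrix=matrix,
        label=label or first.label,
    )


def conformer_ratio(
    dist: CCSDistribution, boundary: float
) -> tuple[float, float]:
    """(compact, extended) population fractions split at a CCS boundary.

    Fractions are trapezoid-integrated intensity below/above the boundary,
    normalized to sum to 1; invariant to uniform intensity scaling.
    """
    total = float(np.trapezoid(dist.intensity, dist.ccs))
    if total <= 0:
        raise ValueError("CCS distribution has zero total intensity")
    if boundary <= dist.ccs[0]:
        return 0.0, 1.0
    if boundary >= dist.ccs[-1]:
        return 1.0, 0.0
    # split the grid exactly at the boundary by inserting an interpolated point
    idx = int(np.searchsorted(dist.ccs, boundary))
    y_b = float(np.interp(boundary, dist.ccs, dist.intensity))
    ccs_lo = np.concatenate([dist.ccs[:idx], [boundary]])
    int_lo = np.concatenate([dist.intensity[:idx], [y_b]])
    compact = float(np.trapezoid(int_lo, ccs_lo)) / total
    compact = min(max(compact, 0.0), 1.0)
    return compact, 1.0 - compact


def default_boundary(fp: CIUFingerprint, smooth_sigma: float = 2.0) -> float:
    """Boundary between conformer families: the minimum of the CE-summed
    distribution between its two largest modes."""
    summed = fp.matrix.sum(axis=1)
    if smooth_sigma > 0:
        summed = ndimage.gaussian_filter1d(summed, smooth_sigma)
    peaks, props = signal.find_peaks(summed, prominence=0.02 * summed.max())
    if peaks.size < 2:
        raise ValueError(
            "fewer than two conformer modes detected; supply an explicit boundary"
        )
    top2 = peaks[np.argsort(summed[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(summed[lo : hi + 1]))
    return float(fp.ccs_axis[valley])


def extended_fraction_curve(fp: CIUFingerprint, boundary: float) -> np.ndarray:
    """Extended-conformer fraction at each collision energy."""
    out = np.empty(fp.ce_axis.size)
    for j in range(fp.ce_axis.size):
        _, ext = conformer_ratio(fp.column(j), boundary)
        out[j] = ext
    return out
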