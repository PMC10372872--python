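"""Survival-yield analysis: gas-phase stability from CID breakdown curves.

The survival yield SY = precursor / (precursor + products) is recorded as a
function of activation energy. Lab-frame energy z*V_trap is normalized to the
center-of-mass frame, E_com = z*V*m_gas/(m_gas + m_ion), so that ions of
different charge and mass are comparable. SY(E_com) is fit with a descending
sigmoid whose midpoint E50 quantifies ion stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "ARGON_MASS",
    "SurvivalYieldCurve",
    "SigmoidFit",
    "e_com",
    "survival_yield",
    "fit_e50",
    "sigmoid",
]

#: Mass of argon, the trap collision gas (Da).
ARGON_MASS = 39.948


def e_com(z: int, v_lab: float, gas_mass: float, ion_mass: float) -> float:
    """Center-of-mass collision energy (eV) of a z+ ion at trap voltage v_lab.

    E_lab = z * V_trap (eV); E_com = E_lab * m_gas / (m_gas + m_ion).
    """
    if z <= 0 or gas_mass <= 0 or ion_mass <= 0 or v_lab < 0:
        raise ValueError("charge, masses must be positive and voltage non-negative")
    return z * v_lab * gas_mass / (gas_mass + ion_mass)


def survival_yield(precursor_intensity: float, product_intensity: float) -> float:
    """Fraction of precursor ions that did not fragment."""
    if precursor_intensity < 0 or product_intensity < 0:
        raise ValueError("intensities must be non-negative")
    total = precursor_intensity + product_intensity
    if total == 0:
        raise ValueError("precursor and product intensities are both zero")
    return precursor_intensity / total


@dataclass(eq=False)
class SurvivalYieldCurve:
    """SY fractions on an ascending E_com grid for one precursor ion."""

    e_com: np.ndarray  # eV
    sy: np.ndarray  # fractions in [0, 1]
    label: str = ""

    def __post_init__(self) -> None:
        self.e_com = np.asarray(self.e_com, float)
        self.sy = np.asarray(self.sy, float)
        if self.e_com.shape != self.sy.shape or self.e_com.ndim != 1:
            raise ValueError("e_com and sy must be matching 1-d arrays")
        if np.any(self.e_com < 0) or np.any(np.diff(self.e_com) <= 0):
            raise ValueError("e_com must be non-negative and strictly ascending")
        if np.any((self.sy < 0) | (self.sy > 1)):
            raise ValueError("survival yields must lie in [0, 1]")


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted SY(E) = bottom + (top - bottom) / (1 + exp((E - e50)/w))."""

    e50: float  # eV
    width: float  # eV, > 0
    top: float
    bottom: float
    stderr_e50: float
    rmse: float

    def __call__(self, e):
        return sigmoid(np.asarray(e, float), self.e50, self.width, self.top, self.bottom)


def sigmoid(e, e50: float, width: float, top: float, bottom: float):
    return bottom + (top - bottom) / (1.0 + np.exp((e - e50) / width))


def fit_e50(curve: SurvivalYieldCurve, min_dynamic_range: float = 0.5) -> SigmoidFit:
    """Nonlinear least-squares sigmoid fit; E50 is the stability midpoint.

    Requires >= 5 points spanning at least ``min_dynamic_range`` in SY.
    Initial guesses: e50 at the point nearest SY = 0.5, width a quarter of
    the energy span; asymptotes free within [0, 1.2].
    """
    e, sy = curve.e_com, curve.sy
    if e.size < 5:
        raise ValueError("sigmoid fit needs at least five points")
    if np.ptp(sy) < min_dynamic_range:
        raise ValueError(
            f"survival yield spans only {np.ptp(sy):.3f}; "
            f"need >= {min_dynamic_range} for a trustworthy midpoint"
        )
    span = float(np.ptp(e))
    e50_0 = float(e[np.argmin(np.abs(sy - 0.5))])
    p0 = [e50_0, span / 4.0, float(sy.max()), float(sy.min())]
    spacing = span / (e.size - 1)
    bounds = (
        [e[0] - spacing, 1e-6, 0.0, 0.0],
        [e[-1] + spacing, span * 2.0, 1.2, 1.2],
    )
    try:
        popt, pcov = optimize.curve_fit(
            sigmoid, e, sy, p0=p0, bounds=bounds, maxfev=20_000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as err:
        raise ValueError(f"sigmoid fit did not converge: {err}") from err
    e50, width, top, bottom = (float(v) for v in popt)
    stderr = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    rmse = float(np.sqrt(np.mean((sigmoid(e, *popt) - sy) ** 2)))
    return SigmoidFit(
        e50=e50, width=width, top=top, bottom=bottom, stderr_e50=stderr, rmse=rmse
    )
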