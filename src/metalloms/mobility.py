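"""Traveling-wave ion-mobility CCS calibration and CCS distributions.

TW drift times have no closed-form relation to collision cross section, so
the axis is calibrated empirically against proteins of known CCS (here:
ubiquitin, cytochrome c, beta-lactoglobulin by default). The standard
power-law protocol is used:

    t'   = t - EDC * sqrt(m/z) / 1000          (mass-dependent flight delay)
    CCS' = CCS_ref * sqrt(mu) / z              (reduced-mass/charge scaling)
    ln CCS' = ln A + B ln t'                   (least squares)

with mu the ion-gas reduced mass. An unknown ion's arrival-time distribution
is then mapped point-wise through CCS = A * t'^B * z / sqrt(mu). Intensities
are copied without a Jacobian correction, matching common practice for
apex/FWHM reporting.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .chem import PROTON_MASS

__all__ = [
    "N2_MASS",
    "CalibrantEntry",
    "CCSCalibration",
    "ArrivalTimeDistribution",
    "CCSDistribution",
    "reduced_mass",
    "calibrate",
    "atd_to_ccs",
    "summarize",
    "load_reference_ccs",
]

#: Mass of molecular nitrogen, the TW drift gas (Da).
N2_MASS = 28.0134


@dataclass(frozen=True)
class CalibrantEntry:
    """One calibrant ion: reference CCS (N2, A^2) and measured arrival time."""

    name: str
    charge: int
    mass: float  # neutral mass, Da
    ccs_ref: float  # A^2
    arrival_time: float  # ms

    def __post_init__(self) -> None:
        if min(self.charge, self.mass, self.ccs_ref, self.arrival_time) <= 0:
            raise ValueError(f"calibrant {self.name!r} has a non-positive field")

    @property
    def mz(self) -> float:
        return (self.mass + self.charge * PROTON_MASS) / self.charge


@dataclass(frozen=True)
class CCSCalibration:
    """Fitted TW power law CCS = A * t'^B * z / sqrt(mu), with diagnostics."""

    a: float
    b: float
    edc: float
    gas_mass: float = N2_MASS
    tw_set: str | None = None
    r_squared: float = float("nan")
    residuals: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("calibration requires A > 0 and B > 0")

    def corrected_time(self, t, mz: float):
        return np.asarray(t, float) - self.edc * np.sqrt(mz) / 1000.0

    def ccs(self, t, mass: float, charge: int):
        """Map arrival times (ms) to CCS (A^2) for an ion of known identity."""
        mz = (mass + charge * PROTON_MASS) / charge
        t_prime = self.corrected_time(t, mz)
        mu = reduced_mass(mass, self.gas_mass)
        return self.a * np.power(t_prime, self.b) * charge / np.sqrt(mu)

    def inverse(self, ccs, mass: float, charge: int):
        """Arrival time (ms) at which an ion of given CCS would appear."""
        mz = (mass + charge * PROTON_MASS) / charge
        mu = reduced_mass(mass, self.gas_mass)
        t_prime = np.power(
            np.asarray(ccs, float) * np.sqrt(mu) / (self.a * charge), 1.0 / self.b
        )
        return t_prime + self.edc * np.sqrt(mz) / 1000.0


@dataclass(eq=False)
class ArrivalTimeDistribution:
    """Intensity versus drift time (ms) for one quadrupole-selected ion."""

    times: np.ndarray
    intensity: np.ndarray
    label: str = ""
    charge: int = 0
    mass: float = 0.0  # neutral mass, Da
    tw_set: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.times.ndim != 1 or self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must be matching 1-d arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(eq=False)
class CCSDistribution:
    """Intensity versus CCS (A^2); apex and FWHM filled in by ``summarize``."""

    ccs: np.ndarray
    intensity: np.ndarray
    label: str = ""
    charge: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.ccs = np.asarray(self.ccs, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.ccs.ndim != 1 or self.ccs.shape != self.intensity.shape:
            raise ValueError("ccs and intensity must be matching 1-d arrays")
        if self.ccs.size and np.any(np.diff(self.ccs) <= 0):
            raise ValueError("CCS grid must be strictly ascending")


def reduced_mass(ion_mass: float, gas_mass: float) -> float:
    return ion_mass * gas_mass / (ion_mass + gas_mass)


def calibrate(
    entries: list[CalibrantEntry],
    edc: float,
    gas_mass: float = N2_MASS,
    tw_set: str | None = None,
) -> CCSCalibration:
    """Fit the TW power law to >= 3 calibrant ions.

    The EDC (enhanced duty cycle) delay coefficient and drift gas are
    required inputs: they are instrument settings with no safe default.
    """
    if len(entries) < 3:
        raise ValueError("TW calibration needs at least three calibrant ions")
    t_prime = np.empty(len(entries))
    ccs_prime = np.empty(len(entries))
    for i, e in enumerate(entries):
        tp = e.arrival_time - edc * np.sqrt(e.mz) / 1000.0
        if tp <= 0:
            raise ValueError(
                f"calibrant {e.name!r} (z={e.charge}) has non-positive corrected "
                f"drift time {tp:.4f} ms"
            )
        t_prime[i] = tp
        mu = reduced_mass(e.mass, gas_mass)
        ccs_prime[i] = e.ccs_ref * np.sqrt(mu) / e.charge
    x = np.log(t_prime)
    y = np.log(ccs_prime)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate calibration: all corrected times identical")
    b, ln_a = np.polyfit(x, y, 1)
    if b <= 0:
        raise ValueError(f"calibration slope B={b:.4f} is not positive")
    fitted = ln_a + b * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CCSCalibration(
        a=float(np.exp(ln_a)),
        b=float(b),
        edc=edc,
        gas_mass=gas_mass,
        tw_set=tw_set,
        r_squared=r2,
        residuals=tuple(np.exp(y) - np.exp(fitted)),
    )


def atd_to_ccs(atd: ArrivalTimeDistribution, cal: CCSCalibration) -> CCSDistribution:
    """Map an arrival-time distribution to a CCS distribution.

    Times whose EDC-corrected value is non-positive are dropped (their count
    is reported on the result and as a warning). Calibrations tagged with a
    TW parameter set are never applied to ATDs from a different set.
    """
    if atd.charge <= 0 or atd.mass <= 0:
        raise ValueError("ATD must carry the ion's charge and neutral mass")
    if cal.tw_set is not None and atd.tw_set is not None and cal.tw_set != atd.tw_set:
        raise ValueError(
            f"TW parameter set mismatch: calibration {cal.tw_set!r} vs ATD {atd.tw_set!r}"
        )
    mz = (atd.mass + atd.charge * PROTON_MASS) / atd.charge
    t_prime = cal.corrected_time(atd.times, mz)
    keep = t_prime > 0
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} arrival-time points with non-positive "
            "corrected drift time",
            stacklevel=2,
        )
    if not np.any(keep):
        raise ValueError("no arrival-time points survive the EDC correction")
    ccs = cal.ccs(atd.times[keep], atd.mass, atd.charge)
    return CCSDistribution(
        ccs=ccs,
        intensity=atd.intensity[keep],
        label=atd.label,
        charge=atd.charge,
        n_dropped=n_dropped,
    )


def summarize(
    ccsd: CCSDistribution, smooth_sigma: float = 2.0
) -> tuple[float, float]:
    """Apex (A^2) and FWHM (A^2) of the main mode.

    The distribution is Gaussian-smoothed (``smooth_sigma`` in grid steps)
    before taking the apex; ties go to the lowest CCS. FWHM is found by
    linear interpolation at half maximum on each flank of the apex mode; a
    delta-like single-bin mode reports one grid step by convention. Both
    statistics are invariant to uniform intensity scaling.
    """
    if ccsd.ccs.size == 0 or not np.any(ccsd.intensity > 0):
        raise ValueError("cannot summarize an empty or all-zero CCS distribution")
    smooth = (
        ndimage.gaussian_filter1d(ccsd.intensity, smooth_sigma)
        if smooth_sigma > 0
        else ccsd.intensity.astype(float)
    )
    apex_idx = int(np.argmax(smooth))  # argmax returns the first (lowest-CCS) tie
    apex = float(ccsd.ccs[apex_idx])
    half = smooth[apex_idx] / 2.0
    step = float(np.median(np.diff(ccsd.ccs))) if ccsd.ccs.size > 1 else 0.0

    def _cross(indices) -> float | None:
        prev = apex_idx
        for i in indices:
            if smooth[i] <= half:
                # linear interpolation between i and prev
                x0, x1 = ccsd.ccs[i], ccsd.ccs[prev]
                y0, y1 = smooth[i], smooth[prev]
                if y1 == y0:
                    return float(x0)
                return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
            prev = i
        return None

    left = _cross(range(apex_idx - 1, -1, -1))
    right = _cross(range(apex_idx + 1, len(smooth)))
    if left is None and right is None:
        fwhm = step if step > 0 else 0.0
    elif left is None:
        fwhm = 2.0 * (right - apex)
    elif right is None:
        fwhm = 2.0 * (apex - left)
    else:
        fwhm = right - left
    if fwhm <= 0:
        fwhm = step
    return apex, float(fwhm)


def load_reference_ccs() -> pd.DataFrame:
    """Bundled default calibrant reference table (protein, charge, mass, CCS)."""
    path = importlib.resources.files("metalloms.data") / "calibrants_n2.csv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")
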