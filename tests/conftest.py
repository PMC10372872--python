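import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metalloms.chem import MetalComplexSpecies, load_mt3
from metalloms.mobility import N2_MASS, CCSCalibration, CalibrantEntry, calibrate, reduced_mass

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mt3():
    return load_mt3()


@pytest.fixture(scope="session")
def cu4zn4ox(mt3):
    """The predominant product of the Cu(II) + Zn7MT3 reaction."""
    return MetalComplexSpecies(mt3, 4, 4, 2)


@pytest.fixture(scope="session")
def zn7red(mt3):
    """Fully reduced, fully zinc-loaded metallothionein-3."""
    return MetalComplexSpecies(mt3, 0, 7, 0)


def synthetic_calibrants(a=200.0, b=0.55, edc=1.35, gas_mass=N2_MASS):
    """Calibrant entries generated exactly from a known TW power law."""
    entries = []
    for name, z, mass, t in [
        ("ubiquitin", 4, 8565.8, 5.0),
        ("ubiquitin", 5, 8565.8, 4.1),
        ("cytochrome_c", 6, 12358.3, 6.2),
        ("cytochrome_c", 7, 12358.3, 5.6),
        ("beta_lactoglobulin", 7, 18363.3, 8.4),
    ]:
        mz = (mass + z * 1.007276) / z
        t_prime = t - edc * np.sqrt(mz) / 1000.0
        ccs = a * t_prime**b * z / np.sqrt(reduced_mass(mass, gas_mass))
        entries.append(CalibrantEntry(name, z, mass, ccs, t))
    return entries


@pytest.fixture(scope="session")
def tw_calibration() -> CCSCalibration:
    return calibrate(synthetic_calibrants(), edc=1.35)
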