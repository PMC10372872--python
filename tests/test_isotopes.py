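import itertools

import numpy as np
import pytest

from metalloms.chem import PROTON_MASS, isotope_table
from metalloms.isotopes import (
    IsotopePattern,
    isotope_pattern,
    render_on_grid,
    render_profile,
    to_mz,
)


def brute_force_pattern(counts: dict, bin_width: float = 1e-4):
    """Exact multinomial enumeration over every isotope assignment.

    Only feasible for a handful of atoms; serves as the independent oracle
    for the convolution-with-pruning implementation.
    """
    table = isotope_table()
    atoms = []
    for element, n in counts.items():
        masses, abundances = table[element]
        atoms.extend([list(zip(masses, abundances))] * n)
    sticks: dict[int, list] = {}
    accumulated: dict[int, float] = {}
    weighted: dict[int, float] = {}
    for assignment in itertools.product(*atoms):
        mass = sum(m for m, _ in assignment)
        ab = np.prod([a for _, a in assignment])
        key = round(mass / bin_width)
        accumulated[key] = accumulated.get(key, 0.0) + ab
        weighted[key] = weighted.get(key, 0.0) + mass * ab
    keys = sorted(accumulated)
    masses = np.array([weighted[k] / accumulated[k] for k in keys])
    abundances = np.array([accumulated[k] for k in keys])
    return masses, abundances / abundances.sum()


class TestPatternOracle:
    @pytest.mark.parametrize(
        "counts",
        [
            {"H": 1},
            {"H": 2},
            {"H": 2, "O": 1},
            {"C": 3, "H": 5, "N": 1, "O": 1},
            {"S": 4},
            {"Cu": 2, "Zn": 2},
            {"C": 2, "S": 2, "Cu": 1, "Zn": 1},
        ],
    )
    def test_matches_brute_force_enumeration(self, counts):
        oracle_mass, oracle_ab = brute_force_pattern(counts)
        pattern = isotope_pattern(counts, prune=0.0)
        assert pattern.positions == pytest.approx(oracle_mass, abs=1e-9)
        assert pattern.abundances == pytest.approx(oracle_ab, abs=1e-12)

    def test_h1_table_lookup(self):
        pattern = isotope_pattern({"H": 1})
        assert pattern.abundances == pytest.approx([0.999885, 0.000115])

    def test_h2_base_peak(self):
        pattern = isotope_pattern({"H": 2})
        assert pattern.base_position == pytest.approx(2.01565, abs=1e-5)
        assert pattern.abundances.max() == pytest.approx(0.999885**2, abs=1e-9)

    def test_zn_matches_bundled_table(self):
        pattern = isotope_pattern({"Zn": 1})
        masses, abundances = isotope_table()["Zn"]
        assert len(pattern) == 5
        assert pattern.positions == pytest.approx(masses)
        assert pattern.abundances == pytest.approx(abundances / abundances.sum())

    def test_convolution_factorizes(self):
        """pattern(A+B) equals pattern(A) convolved with pattern(B)."""
        a, b = {"C": 5, "S": 1}, {"Zn": 1, "H": 8}
        combined = isotope_pattern({"C": 5, "S": 1, "Zn": 1, "H": 8}, prune=0.0)
        pa = isotope_pattern(a, prune=0.0)
        pb = isotope_pattern(b, prune=0.0)
        masses = (pa.positions[:, None] + pb.positions[None, :]).ravel()
        ab = (pa.abundances[:, None] * pb.abundances[None, :]).ravel()
        oracle_mass, oracle_ab = {}, {}
        for m, x in zip(masses, ab):
            key = round(m / 1e-4)
            oracle_ab[key] = oracle_ab.get(key, 0.0) + x
            oracle_mass[key] = oracle_mass.get(key, 0.0) + m * x
        keys = sorted(oracle_ab)
        assert combined.positions == pytest.approx(
            [oracle_mass[k] / oracle_ab[k] for k in keys], abs=1e-9
        )
        assert combined.abundances == pytest.approx(
            [oracle_ab[k] for k in keys], abs=1e-10
        )

    def test_pruning_retains_nearly_all_abundance(self, mt3):
        from metalloms.chem import composition_from_sequence

        pattern = isotope_pattern(composition_from_sequence(mt3))
        assert pattern.retained >= 0.999

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError):
            isotope_pattern({"Uub": 1})


class TestToMz:
    def test_proton_arithmetic(self):
        pattern = IsotopePattern(np.array([6900.0]), np.array([1.0]))
        assert to_mz(pattern, 5).positions[0] == pytest.approx(1381.007276, abs=1e-6)

    def test_single_protonation(self):
        pattern = IsotopePattern(np.array([100.0]), np.array([1.0]))
        assert to_mz(pattern, 1).positions[0] == pytest.approx(100.0 + PROTON_MASS)

    def test_rejects_nonpositive_charge(self):
        pattern = IsotopePattern(np.array([100.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            to_mz(pattern, 0)

    def test_rejects_double_conversion(self):
        pattern = to_mz(IsotopePattern(np.array([100.0]), np.array([1.0])), 2)
        with pytest.raises(ValueError, match="m/z"):
            to_mz(pattern, 2)


class TestRenderProfile:
    def _one_stick(self, mz=1000.0, abundance=1.0):
        return IsotopePattern(
            np.array([mz]), np.array([abundance]), domain="m/z", charge=1
        )

    def test_single_peak_integral_matches_abundance(self):
        spectrum = render_profile(self._one_stick(), resolving_power=10_000)
        area = np.trapezoid(spectrum.intensity, spectrum.mz)
        assert area == pytest.approx(1.0, rel=1e-3)

    def test_doubling_resolving_power_halves_fwhm(self):
        def fwhm(rp):
            s = render_profile(self._one_stick(), resolving_power=rp, grid_step=0.001)
            half = s.intensity.max() / 2
            above = s.mz[s.intensity >= half]
            return above[-1] - above[0]

        # measured widths are quantized to the grid, so allow two steps
        assert fwhm(40_000) == pytest.approx(fwhm(20_000) / 2, abs=0.002)

    def test_well_separated_sticks_resolve(self):
        fwhm = 1000.0 / 20_000
        pattern = IsotopePattern(
            np.array([1000.0, 1000.0 + 10 * fwhm]),
            np.array([0.5, 0.5]),
            domain="m/z",
            charge=1,
        )
        spectrum = render_profile(pattern, resolving_power=20_000)
        interior = spectrum.intensity[1:-1]
        n_maxima = int(
            np.sum(
                (interior > spectrum.intensity[:-2])
                & (interior > spectrum.intensity[2:])
            )
        )
        assert n_maxima == 2

    def test_rejects_neutral_domain(self):
        pattern = IsotopePattern(np.array([1000.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            render_profile(pattern)
        with pytest.raises(ValueError):
            render_on_grid(pattern, np.linspace(999, 1001, 10))

    def test_rejects_nonpositive_grid_step(self):
        with pytest.raises(ValueError):
            render_profile(self._one_stick(), grid_step=0.0)
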