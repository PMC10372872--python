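import numpy as np
import pytest

from metalloms.chem import ProteinSequence, composition_from_sequence, monoisotopic_mass
from metalloms.topdown import (
    FragmentIon,
    FragmentMatch,
    generate_fragments,
    localize_metals,
    match_fragments,
)

M_H = monoisotopic_mass({"H": 1})
M_ZN = monoisotopic_mass({"Zn": 1})
M_CU = monoisotopic_mass({"Cu": 1})
WATER = monoisotopic_mass({"H": 2, "O": 1})
PROTON = 1.007276


def ion(series, index, mz=0.0, charge=1, **adducts):
    return FragmentIon(series=series, index=index, charge=charge, mz=mz, **adducts)


def fake_match(fragment):
    return FragmentMatch(fragment=fragment, observed_mz=fragment.mz, ppm_error=0.0, intensity=1.0)


class TestGenerate:
    def test_y1_lysine(self):
        frags = generate_fragments(ProteinSequence("AK"))
        y1 = next(f for f in frags if f.series == "y" and f.index == 1)
        assert y1.mz == pytest.approx(147.1128, abs=1e-4)

    def test_b2_of_md(self):
        frags = generate_fragments(ProteinSequence("MDA"))
        b2 = next(f for f in frags if f.series == "b" and f.index == 2)
        assert b2.mz == pytest.approx(247.0747, abs=1e-4)

    def test_zinc_adduct_displaces_two_hydrogens(self):
        frags = generate_fragments(ProteinSequence("CCGK"), zn_range=(0, 1))
        y3_free = next(
            f for f in frags if f.series == "y" and f.index == 3 and f.n_zn == 0
        )
        y3_zn = next(
            f for f in frags if f.series == "y" and f.index == 3 and f.n_zn == 1
        )
        assert y3_zn.mz - y3_free.mz == pytest.approx(M_ZN - 2 * M_H, abs=1e-9)

    def test_water_loss_subtracts_water(self):
        frags = generate_fragments(ProteinSequence("GAK"), allow_water_loss=True)
        y2 = {f.water_loss: f for f in frags if f.series == "y" and f.index == 2}
        assert y2[0].mz - y2[1].mz == pytest.approx(WATER, abs=1e-9)

    def test_cys_budget_excludes_impossible_adducts(self):
        # one Cys in the suffix: no disulfide, at most one metal
        frags = generate_fragments(
            ProteinSequence("GGCK"), cu_range=(0, 2), zn_range=(0, 1), ss_range=(0, 1)
        )
        y2_states = {
            (f.n_cu, f.n_zn, f.n_ss) for f in frags if f.series == "y" and f.index == 2
        }
        assert y2_states == {(0, 0, 0), (1, 0, 0), (0, 1, 0)}

    def test_by_complementarity(self, mt3):
        """neutral(b_i) + neutral(y_{L-i}) equals the intact neutral mass."""
        frags = generate_fragments(mt3, max_charge=1)
        by_key = {(f.series, f.index): f for f in frags}
        total = monoisotopic_mass(composition_from_sequence(mt3))
        for i in range(1, len(mt3)):
            b = by_key[("b", i)]
            y = by_key[("y", len(mt3) - i)]
            neutral_sum = (b.mz - PROTON) + (y.mz - PROTON)
            assert neutral_sum == pytest.approx(total, abs=1e-6)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            generate_fragments(ProteinSequence("K"))


class TestMatch:
    def test_signed_ppm_within_tolerance(self):
        frag = ion("y", 1, mz=1000.0)
        matches = match_fragments([(1000.0150, 5.0)], [frag], tol_ppm=20.0)
        assert len(matches) == 1
        assert matches[0].ppm_error == pytest.approx(15.0, abs=1e-6)

    def test_outside_tolerance_unmatched(self):
        frag = ion("y", 1, mz=1000.0)
        assert match_fragments([(1000.0300, 5.0)], [frag], tol_ppm=20.0) == []

    def test_one_to_one_greedy_by_ppm(self):
        close = ion("y", 1, mz=1000.0000)
        far = ion("y", 2, mz=1000.0100)
        matches = match_fragments([(1000.0040, 1.0)], [close, far], tol_ppm=20.0)
        assert len(matches) == 1
        assert matches[0].fragment.index == 1  # 4 ppm beats 6 ppm

    def test_tie_prefers_simpler_adduct_state(self):
        plain = ion("y", 1, mz=1000.0)
        metalated = ion("y", 2, mz=1000.0, n_zn=1)
        matches = match_fragments([(1000.0, 1.0)], [metalated, plain], tol_ppm=20.0)
        assert matches[0].fragment.n_zn == 0

    def test_every_match_respects_tolerance(self, mt3):
        rng = np.random.default_rng(11)
        frags = generate_fragments(mt3, max_charge=2, zn_range=(0, 1))
        peaks = [
            (f.mz * (1 + rng.uniform(-30, 30) * 1e-6), 1.0)
            for f in rng.choice(len(frags), size=200, replace=False).astype(int)
            for f in [frags[f]]
        ]
        for match in match_fragments(peaks, frags, tol_ppm=20.0):
            assert abs(match.ppm_error) <= 20.0


class TestLocalize:
    def test_metal_free_y_series_confines_cu_to_n_terminus(self):
        """Metal-free y2..y30 on a 68-residue protein confines Cu to [1, 38]."""
        matches = [fake_match(ion("y", i, mz=500.0 + i)) for i in range(2, 31)]
        assignment = localize_metals(matches, seq_length=68, boundary=38)
        cu = assignment.metals["cu"]
        assert cu.free_suffix == 30
        assert cu.interval == (1, 38)
        assert cu.domain == "beta"
        assert not cu.inconsistent

    def test_no_matches_leave_interval_unconstrained(self):
        assignment = localize_metals([], seq_length=68, boundary=31)
        assert assignment.metals["cu"].interval == (1, 68)
        assert assignment.metals["zn"].interval == (1, 68)

    def test_partial_metalation_voids_suffix_without_flag(self):
        """Zn-bearing and Zn-free y30 coexist: both precursor populations are
        real, so the suffix is not metal-free evidence but nothing is flagged."""
        matches = [
            fake_match(ion("y", 30, mz=1100.0)),
            fake_match(ion("y", 30, mz=1130.0, n_zn=1)),
        ]
        assignment = localize_metals(matches, seq_length=68, boundary=31)
        zn = assignment.metals["zn"]
        assert zn.free_suffix == 0
        assert zn.interval == (1, 68)  # interval keeps the suffix residues
        assert not zn.inconsistent

    def test_strictly_nested_contradiction_is_flagged(self):
        matches = [
            fake_match(ion("y", 30, mz=1100.0)),
            fake_match(ion("y", 10, mz=400.0, n_zn=1)),
        ]
        assignment = localize_metals(matches, seq_length=68, boundary=31)
        assert assignment.metals["zn"].inconsistent

    def test_b_ions_constrain_the_prefix(self):
        matches = [fake_match(ion("b", i, mz=300.0 + i)) for i in range(1, 6)]
        assignment = localize_metals(matches, seq_length=68, boundary=31)
        assert assignment.metals["cu"].free_prefix == 5
        assert assignment.metals["cu"].interval == (6, 68)

    def test_bad_boundary_rejected(self):
        with pytest.raises(ValueError):
            localize_metals([], seq_length=68, boundary=68)

    def test_localization_sound_on_random_ground_truth(self):
        """Inferred intervals always contain every true metal position."""
        rng = np.random.default_rng(202)
        length = 68
        for _ in range(100):
            positions = sorted(rng.choice(np.arange(1, 32), size=4, replace=False))
            observed_y = rng.choice(np.arange(1, length), size=20, replace=False)
            matches = []
            for k in map(int, observed_y):
                bearing = sum(1 for p in positions if p >= length - k + 1)
                matches.append(
                    fake_match(ion("y", k, mz=100.0 + k, n_cu=bearing))
                )
            interval = localize_metals(matches, length, boundary=31).metals["cu"].interval
            assert interval[0] <= positions[0]
            assert interval[1] >= positions[-1]
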