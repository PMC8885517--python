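"""Compositions, masses and counterpart derivation under ¹⁵N labeling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pt_mass

from n15quant import chemcore as cc


# Label multiplicities: arginine 4, histidine 3, K/N/Q/W 2, everything else 1.
EXPECTED_NITROGENS = {
    **{aa: 1 for aa in "ADEFGILMPSTVYC"},
    "K": 2, "N": 2, "Q": 2, "W": 2, "H": 3, "R": 4,
}


@pytest.mark.parametrize("aa,expected", sorted(EXPECTED_NITROGENS.items()))
def test_residue_nitrogens_match_label_multiplicities(aa, expected):
    assert cc.residue_nitrogens(aa) == expected


def test_residue_nitrogens_consistent_with_formulas():
    """The label-multiplicity table and the elemental formula table agree."""
    for aa in EXPECTED_NITROGENS:
        assert cc.residue_nitrogens(aa) == cc.residue_formula(aa)["N"]


@pytest.mark.parametrize("bad", ["B", "Z", "X", "U", "1"])
def test_ambiguous_residues_rejected(bad):
    with pytest.raises(cc.UnknownResidueError, match=repr(bad)):
        cc.residue_nitrogens(bad)


class TestBuildComposition:
    def test_worked_example_reproduces_printed_formula(self, worked_heavy_comp):
        """Singly protonated carbamidomethylated VALEACVQAR: C46 H82 O15 S1,
        15 nitrogens split 14 labeled + 1 unlabeled (the reagent N)."""
        comp = worked_heavy_comp
        assert comp["C"] == 46
        assert comp["H"] == 82
        assert comp["O"] == 15
        assert comp["S"] == 1
        assert comp["N"] == 15
        assert comp.n_labeled_N == 14
        assert comp.n_unlabeled_N == 1

    def test_neutral_light_glycine_is_free_amino_acid(self):
        comp = cc.build_composition(cc.PeptideIon("G", charge=0, channel="light"))
        assert comp.counts == {"C": 2, "H": 5, "N": 1, "O": 2}
        assert comp.n_labeled_N == 0

    def test_channels_share_element_counts(self, rng):
        from conftest import random_tryptic_sequence

        for _ in range(20):
            seq = random_tryptic_sequence(rng)
            z = int(rng.integers(1, 4))
            light = cc.build_composition(cc.PeptideIon(seq, charge=z, channel="light"))
            heavy = cc.build_composition(cc.PeptideIon(seq, charge=z, channel="heavy"))
            assert light.counts == heavy.counts
            assert light.n_labeled_N == 0
            assert light.n_unlabeled_N == light["N"]
            assert heavy.n_labeled_N + heavy.n_unlabeled_N == heavy["N"]
            assert heavy.n_labeled_N == sum(cc.residue_nitrogens(aa) for aa in seq)

    def test_unknown_modification_lists_supported_names(self):
        ion = cc.PeptideIon("GK", (((1), "Phospho"),), 1, "light")
        with pytest.raises(cc.UnknownModificationError, match="Carbamidomethyl"):
            cc.build_composition(ion)

    def test_combined_modification_names(self):
        """Met-loss+Acetyl resolves as the sum of both deltas."""
        plain = cc.build_composition(cc.PeptideIon("MGK", charge=0, channel="heavy"))
        modded = cc.build_composition(
            cc.PeptideIon("MGK", cc.parse_modifications("Met-loss+Acetyl@Nterm"), 0, "heavy")
        )
        delta = {el: modded[el] - plain[el] for el in "CHNOS"}
        assert delta == {"C": -3, "H": -7, "N": -1, "O": 0, "S": -1}
        assert modded.n_labeled_N == plain.n_labeled_N - 1

    def test_pyro_glu_removes_a_labeled_nitrogen(self):
        plain = cc.build_composition(cc.PeptideIon("QGK", charge=0, channel="heavy"))
        pyro = cc.build_composition(
            cc.PeptideIon("QGK", cc.parse_modifications("Gln->pyro-Glu@1"), 0, "heavy")
        )
        assert pyro["N"] == plain["N"] - 1
        assert pyro.n_labeled_N == plain.n_labeled_N - 1
        assert pyro.n_unlabeled_N == plain.n_unlabeled_N


@settings(max_examples=30, derandomize=True)
@given(
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=10),
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=10),
)
def test_concatenation_additivity(seq_a, seq_b):
    """Composition of a concatenated sequence = sum of parts − one water."""
    water = cc.ElementalComposition({"H": 2, "O": 1})
    a = cc.build_composition(cc.PeptideIon(seq_a, charge=0, channel="heavy"))
    b = cc.build_composition(cc.PeptideIon(seq_b, charge=0, channel="heavy"))
    ab = cc.build_composition(cc.PeptideIon(seq_a + seq_b, charge=0, channel="heavy"))
    combined = a + b - water
    # the water removal takes no nitrogen, so pools add exactly
    assert ab.counts == combined.counts
    assert ab.n_labeled_N == combined.n_labeled_N


class TestMasses:
    def test_heavy_light_shift_is_linear_in_label_count(self, worked_heavy_comp):
        heavy = cc.monoisotopic_mass(worked_heavy_comp, "heavy")
        light = cc.monoisotopic_mass(worked_heavy_comp, "light")
        assert heavy - light == pytest.approx(14 * cc.DELTA_15N, abs=1e-12)

    @pytest.mark.parametrize("seq", ["G", "PEPTIDER", "LTYYTPEYETK"])
    def test_neutral_mass_matches_reference_calculator(self, seq):
        comp = cc.build_composition(cc.PeptideIon(seq, charge=0, channel="light"))
        ours = cc.monoisotopic_mass(comp, "light")
        assert ours == pytest.approx(pt_mass.calculate_mass(sequence=seq), abs=1e-5)

    def test_charge_state_arithmetic(self):
        neutral = cc.build_composition(cc.PeptideIon("PEPTIDER", charge=0, channel="light"))
        mh = cc.build_composition(cc.PeptideIon("PEPTIDER", charge=1, channel="light"))
        mh2 = cc.build_composition(cc.PeptideIon("PEPTIDER", charge=2, channel="light"))
        m = cc.monoisotopic_mass(neutral, "light")
        assert cc.mz(mh, "light") == pytest.approx(m + cc.MASS_PROTON, abs=1e-9)
        assert cc.mz(mh2, "light") == pytest.approx((m + 2 * cc.MASS_PROTON) / 2, abs=1e-9)

    def test_pair_mz_separation_scales_with_charge(self):
        for z in (1, 2, 3):
            ion = cc.PeptideIon("VALEACVQAR", cc.parse_modifications("Carbamidomethyl@6"), z, "heavy")
            comp = cc.build_composition(ion)
            sep = cc.mz(comp, "heavy") - cc.mz(comp, "light")
            assert sep == pytest.approx(14 * cc.DELTA_15N / z, abs=1e-9)


class TestCounterpart:
    def test_channel_flip_preserves_everything_else(self):
        ion = cc.PeptideIon("VALEACVQAR", cc.parse_modifications("Carbamidomethyl@6"), 2, "light")
        twin = cc.counterpart(ion)
        assert twin.channel == "heavy"
        assert (twin.sequence, twin.modifications, twin.charge) == (
            ion.sequence, ion.modifications, ion.charge)

    def test_involution(self, rng):
        from conftest import random_tryptic_sequence

        for _ in range(10):
            ion = cc.PeptideIon(
                random_tryptic_sequence(rng),
                charge=int(rng.integers(1, 4)),
                channel="light" if rng.random() < 0.5 else "heavy",
            )
            assert cc.counterpart(cc.counterpart(ion)) == ion


class TestModificationParsing:
    def test_round_trip(self):
        spec = "Carbamidomethyl@6;Acetyl@Nterm"
        mods = cc.parse_modifications(spec)
        assert mods == ((6, "Carbamidomethyl"), ("Nterm", "Acetyl"))
        assert cc.format_modifications(mods) == spec

    def test_position_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="position"):
            cc.PeptideIon("GK", ((5, "Oxidation"),), 1, "light")

    def test_composition_arithmetic_is_elementwise(self):
        a = cc.ElementalComposition({"C": 2, "N": 1}, 1, 0)
        b = cc.ElementalComposition({"C": 1, "O": 3})
        assert (a + b).counts == {"C": 3, "N": 1, "O": 3}
        assert ((a + b) - b).counts == a.counts

    def test_invalid_nitrogen_split_rejected(self):
        with pytest.raises(ValueError, match="split"):
            cc.ElementalComposition({"N": 2}, n_labeled_N=1, n_unlabeled_N=0)
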