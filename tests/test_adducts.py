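"""Fragment series rules, oxidation-state bookkeeping and label grammar."""

import pytest

from metalpept import (
    PROTON_MASS,
    AdductIon,
    Fragment,
    LabelError,
    MetalMoiety,
    PeptideSequence,
    VO,
    VO2,
    VOL,
    VOL2,
    enumerate_candidates,
    enumerate_fragments,
    format_label,
    monoisotopic_mass,
    neutral_adduct,
    parse_label,
    parse_moiety,
    peptide_composition,
)
from metalpept.adducts import LIGANDS, load_ligand_registry


class TestFragments:
    def test_b6_and_a6_masses(self, at2):
        b6 = AdductIon(base=Fragment("b", 6, at2))
        a6 = AdductIon(base=Fragment("a", 6, at2))
        assert b6.mz() == pytest.approx(784.410, abs=1e-3)
        assert a6.mz() == pytest.approx(756.415, abs=1e-3)
        assert b6.mz() - a6.mz() == pytest.approx(27.995, abs=1e-3)

    def test_z_is_y_minus_ammonia(self, at2):
        y4 = Fragment("y", 4, at2).composition
        z4 = Fragment("z", 4, at2).composition
        assert dict((y4 - z4).counts) == {"N": 1, "H": 3}

    def test_full_length_fragment_rejected(self, at2):
        with pytest.raises(ValueError):
            Fragment("y", len(at2), at2)
        with pytest.raises(ValueError):
            enumerate_fragments(at2, series_set=("y",), index_range=[len(at2)])

    def test_complementarity(self, at1):
        """b_i + y_(n-i) ion masses reconstruct peptide + 2 protons."""
        n = len(at1)
        pep_mass = monoisotopic_mass(peptide_composition(at1.residues))
        for i in range(1, n):
            b = AdductIon(base=Fragment("b", i, at1)).mz()
            y = AdductIon(base=Fragment("y", n - i, at1)).mz()
            assert b + y == pytest.approx(pep_mass + 2 * PROTON_MASS, abs=1e-9)

    def test_enumerate_all_series(self, at2):
        frags = enumerate_fragments(at2)
        assert len(frags) == 4 * (len(at2) - 1)
        assert {f.series for f in frags} == {"a", "b", "y", "z"}


class TestOxidationState:
    @pytest.mark.parametrize(
        "label, os_expected",
        [
            ("[a6 + VO - H]2+", 4),
            ("[y4″ + VO - H]+", 3),
            ("[b6 + VO - 2H]+", 4),
            ("[z5 + VO - H]+", 3),
        ],
    )
    def test_fragment_assignments(self, at1, label, os_expected):
        assert parse_label(label, peptide=at1).oxidation_state == os_expected

    def test_redox_pair_of_precursors(self, at2):
        reduced = parse_label("[AT + VOL + H]2+", peptide=at2)
        oxidized = parse_label("[AT + VOL]2+", peptide=at2)
        assert reduced.oxidation_state == 4
        assert oxidized.oxidation_state == 5

    def test_charge_balance_identity(self, at2):
        """z = protons + OS - 2 n_oxo - n_ligands on every enumerated ion."""
        ions = enumerate_candidates(
            at2, moieties=[VO(), VO2(), VOL("pic"), VOL2("pic")], z_range=(1, 2)
        )
        assert ions
        for ion in ions:
            n_oxo = sum(m.n_oxo for m in ion.moieties)
            n_lig = sum(m.n_ligands for m in ion.moieties)
            assert ion.charge == ion.net_protons + ion.oxidation_state - 2 * n_oxo - n_lig

    def test_multi_vanadium_has_no_single_os(self, at2):
        ion = AdductIon(base=at2, moieties=(VO(), VO()), charge=2, protons_removed=2)
        with pytest.raises(ValueError):
            ion.oxidation_state

    def test_metal_free_ion_has_no_os(self, at2):
        with pytest.raises(ValueError):
            AdductIon(base=at2, charge=1, protons_added=1).oxidation_state


class TestLabels:
    @pytest.mark.parametrize(
        "label",
        [
            "[b6 + VO - 2H]+",
            "[a9 + VO - H]2+",
            "[y4″ + VO - 2H]+",
            "[z3 + VO - H]+",
            "[AT + VO(pic)2]",
            "[M + H]+",
            "[AT2 + VO(pic) + H]2+",
        ],
    )
    def test_round_trip(self, at1, label):
        assert format_label(parse_label(label, peptide=at1)) == label

    def test_format_examples(self, at1):
        ion = AdductIon(base=Fragment("a", 9, at1), moieties=(VO(),),
                        protons_removed=1, charge=2)
        assert format_label(ion) == "[a9 + VO - H]2+"
        mh = AdductIon(base=at1, protons_added=1, charge=1, base_symbol="M")
        assert format_label(mh) == "[M + H]+"

    @pytest.mark.parametrize("bad", ["[b6 VO]", "b6 + VO", "[b6 + VO -]+", "[q3 + VO]+", "[b6 - VO]+"])
    def test_malformed_labels_rejected(self, at1, bad):
        with pytest.raises(LabelError):
            parse_label(bad, peptide=at1)

    def test_y_double_prime_is_plain_y(self, at1):
        assert (
            parse_label("[y4″ + VO - 2H]+", peptide=at1).composition
            == parse_label("[y4 + VO - 2H]+", peptide=at1).composition
        )

    def test_moiety_tokens(self):
        assert parse_moiety("VO2").n_oxo == 2
        assert parse_moiety("VO(pic)2").n_ligands == 2
        assert parse_moiety("VOL2").n_ligands == 2
        assert parse_moiety("2VO").n_v == 2
        with pytest.raises(LabelError):
            parse_moiety("VO(xyz)")


class TestEnumeration:
    def test_vo_adduct_neutral_mass(self, at2):
        """[AT2 + VO - 2H] neutral species mass from enumerated candidates."""
        ions = enumerate_candidates(at2, moieties=[VO()], z_range=(1, 2), q_range=range(4))
        masses = {round(i.neutral_mass, 2) for i in ions}
        assert 1110.46 in masses

    def test_plain_protonation_only(self, at2):
        ions = enumerate_candidates(
            at2, moieties=[None], z_range=(1,), q_range=(0,), p_range=(1,)
        )
        assert len(ions) == 1
        assert ions[0].label == "[M + H]+"

    def test_no_moiety_q0_reduces_to_protonated_fragments(self, at2):
        frags = enumerate_fragments(at2, series_set=("b",))
        ions = enumerate_candidates(
            frags, moieties=[None], z_range=(1,), q_range=(0,), p_range=(0, 1, 2)
        )
        assert {i.label for i in ions} == {f"[b{k}]+" for k in range(1, len(at2))}

    def test_figure4_precursor_present(self, at1):
        ions = enumerate_candidates(at1, moieties=[VOL("pic")], z_range=(2,))
        labels = {i.label for i in ions}
        # the reduced/oxidized precursor pair around [AT1 + VO(pic)]2+
        assert "[M + VO(pic) + H]2+" in labels
        assert "[M + VO(pic)]2+" in labels

    def test_deduplication(self, at2):
        ions = enumerate_candidates(at2, moieties=[VO()], z_range=(1, 2))
        keys = [(i.composition, i.charge) for i in ions]
        assert len(keys) == len(set(keys))


class TestMoietiesAndLigands:
    def test_builtin_ligand_formulas(self):
        assert LIGANDS["pic"].composition.formula() == "C6H4NO2"
        assert LIGANDS["ma"].composition.formula() == "C6H5O3"
        assert LIGANDS["dhp"].composition.formula() == "C7H8NO2"

    def test_moiety_mass_is_sum_of_parts(self):
        m = VOL2("pic")
        expected = (
            parse_moiety("VO").composition.monoisotopic_mass()
            + 2 * LIGANDS["pic"].composition.monoisotopic_mass()
        )
        assert m.composition.monoisotopic_mass() == pytest.approx(expected, abs=1e-9)

    def test_neutral_adduct_proton_displacement(self, at2):
        assert neutral_adduct(at2, parse_moiety("VO")).protons_removed == 2
        assert neutral_adduct(at2, parse_moiety("VO2")).protons_removed == 1
        assert neutral_adduct(at2, parse_moiety("VO(pic)")).protons_removed == 1
        assert neutral_adduct(at2, parse_moiety("VO(pic)2")).protons_removed == 0

    def test_custom_ligand_registry(self, tmp_path):
        cfg = tmp_path / "ligands.yaml"
        cfg.write_text("acac: C5H7O2\n")
        registry = load_ligand_registry(cfg)
        moiety = parse_moiety("VO(acac)2", registry=registry)
        assert moiety.n_ligands == 2
        assert moiety.composition["C"] == 10
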