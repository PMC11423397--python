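"""Deconvolution, peak matching, envelope separation, maps and localization."""

import numpy as np
import pandas as pd
import pytest

from metalpept import (
    PROTON_MASS,
    AdductIon,
    Fragment,
    FragmentationMap,
    Spectrum,
    VO,
    VOL,
    deconvolute,
    enumerate_candidates,
    localize_binding,
    match_peaks,
    nce_stability_profile,
    parse_label,
    peptide_composition,
    resolve_isotopologue_overlap,
    simulate_full_ms,
    simulate_isotopologue_mixture,
    speciation_from_system,
)
from metalpept.annotate import fragmentation_map


class TestDeconvolute:
    def test_two_charge_states_collapse(self):
        m = 1045.534
        sp = Spectrum(
            np.array([(m + 2 * PROTON_MASS) / 2, m + PROTON_MASS]),
            np.array([1e6, 3e5]),
        )
        out = deconvolute(sp, z_range=(1, 2), ppm_tol=10)
        assert len(out) == 1
        assert out.mz[0] == pytest.approx(m, abs=2e-3)
        assert out.intensity[0] == pytest.approx(1.3e6)

    def test_single_peak_forced_z1(self):
        sp = Spectrum(np.array([500.0]), np.array([1.0]))
        out = deconvolute(sp, z_range=(1,))
        assert out.mz[0] == pytest.approx(500.0 - PROTON_MASS, abs=1e-6)

    def test_explicit_charges_honoured(self):
        m = 1045.534
        sp = Spectrum(
            np.array([(m + 2 * PROTON_MASS) / 2, m + PROTON_MASS]),
            np.array([1e6, 3e5]),
            charges=np.array([2, 1]),
        )
        out = deconvolute(sp)
        assert len(out) == 1

    def test_empty_spectrum(self):
        out = deconvolute(Spectrum(np.array([]), np.array([])))
        assert len(out) == 0

    def test_rejects_ms2(self):
        sp = Spectrum(np.array([100.0]), np.array([1.0]), ms_level=2, precursor="x")
        with pytest.raises(ValueError):
            deconvolute(sp)

    def test_recovers_speciation_masses(self, at1):
        """Every planted neutral mass is found within tolerance after
        isotope-resolved simulation (charges inferred, not given)."""
        model = speciation_from_system("AT1/pic")
        spectrum, truth = simulate_full_ms(model, seed=11)
        out = deconvolute(spectrum, z_range=(1, 2, 3, 4), ppm_tol=10)
        for label, mass in truth.neutral_masses.items():
            if truth.species_abundances.get(label, 0) <= 0:
                continue
            err = np.min(np.abs(out.mz - mass)) / mass * 1e6
            assert err < 10, f"{label} not recovered ({err:.1f} ppm off)"


class TestMatchPeaks:
    @pytest.fixture
    def candidates(self, at2):
        return enumerate_candidates(at2, moieties=[None, VO(), VOL("pic")],
                                    z_range=(1, 2))

    def test_ppm_error_sign_and_size(self, at2):
        ion = AdductIon(base=Fragment("b", 6, at2))
        theo = ion.mz()
        obs = theo * (1 + 3.5e-6)
        sp = Spectrum(np.array([obs]), np.array([1.0]))
        (a,) = match_peaks([ion], sp, ppm_tol=10)
        assert a.ppm_error == pytest.approx(3.5, abs=0.01)

    def test_out_of_tolerance_unassigned(self, candidates):
        sp = Spectrum(np.array([849.60]), np.array([1.0]))
        assert match_peaks(candidates, sp, ppm_tol=10) == []

    def test_nearest_candidate_wins(self):
        from metalpept import PeptideSequence

        gln = AdductIon(base=PeptideSequence("Q"), protons_added=1, charge=1)
        lys = AdductIon(base=PeptideSequence("K"), protons_added=1, charge=1)
        obs = gln.mz() + 0.005  # 31 mDa from Lys, 5 mDa from Gln
        sp = Spectrum(np.array([obs]), np.array([1.0]))
        (hit,) = match_peaks([lys, gln], sp, ppm_tol=300, isotopologues=0)
        assert hit.ion.base.residues == "Q"

    def test_empty_candidates_rejected(self):
        sp = Spectrum(np.array([100.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            match_peaks([], sp)

    def test_stable_under_rescaling_and_permutation(self, candidates):
        rng = np.random.default_rng(5)
        theo = np.array([c.mz() for c in candidates[:6]])
        mz = theo * (1 + rng.normal(0, 2e-6, theo.size))
        inten = rng.uniform(1, 100, theo.size)
        order = rng.permutation(theo.size)
        sp1 = Spectrum(mz, inten)
        sp2 = Spectrum(mz[order], 1000.0 * inten[order])
        lab1 = sorted(a.ion.label for a in match_peaks(candidates, sp1))
        lab2 = sorted(a.ion.label for a in match_peaks(candidates, sp2))
        assert lab1 == lab2


class TestOverlapResolution:
    @pytest.fixture
    def forms(self, at2):
        reduced = parse_label("[AT + VO(pic) + H]2+", peptide=at2)
        oxidized = parse_label("[AT + VO(pic)]2+", peptide=at2)
        return reduced, oxidized

    def test_pure_oxidized(self, forms):
        reduced, oxidized = forms
        env, _ = simulate_isotopologue_mixture(reduced, oxidized, 0.0,
                                               noise_cv=0.0, ppm_jitter=0.0)
        fa, fb, resid = resolve_isotopologue_overlap(env, reduced, oxidized)
        assert fa == pytest.approx(0.0, abs=1e-6)
        assert fb == pytest.approx(1.0, abs=1e-6)
        assert resid < 1e-6

    def test_even_mixture_low_noise(self, forms):
        reduced, oxidized = forms
        env, _ = simulate_isotopologue_mixture(reduced, oxidized, 0.5,
                                               noise_cv=0.001, seed=7)
        fa, fb, _ = resolve_isotopologue_overlap(env, reduced, oxidized)
        assert fa == pytest.approx(0.5, abs=0.02)
        assert fa + fb == pytest.approx(1.0, abs=1e-12)

    def test_skewed_mixture_heavy_noise_monte_carlo(self, forms):
        reduced, oxidized = forms
        errs = []
        for seed in range(100):
            env, _ = simulate_isotopologue_mixture(reduced, oxidized, 0.7,
                                                   noise_cv=0.05, seed=seed)
            fa, _, _ = resolve_isotopologue_overlap(env, reduced, oxidized)
            errs.append(abs(fa - 0.7))
        assert max(errs) < 0.05

    def test_scale_invariance(self, forms):
        reduced, oxidized = forms
        env, _ = simulate_isotopologue_mixture(reduced, oxidized, 0.3, seed=1)
        fa1, fb1, _ = resolve_isotopologue_overlap(env, reduced, oxidized)
        scaled = env.replace(intensity=env.intensity * 1e4)
        fa2, fb2, _ = resolve_isotopologue_overlap(scaled, reduced, oxidized)
        assert fa1 == pytest.approx(fa2, abs=1e-12)

    def test_requires_one_hydrogen_difference(self, forms, at2):
        reduced, _ = forms
        other = parse_label("[AT + VO - 2H + H]+", peptide=at2)
        env, _ = simulate_isotopologue_mixture(reduced, forms[1], 0.5)
        with pytest.raises(ValueError):
            resolve_isotopologue_overlap(env, reduced, other)

    def test_degenerate_cluster_rejected(self, forms):
        reduced, oxidized = forms
        env = Spectrum(np.array([617.75]), np.array([0.0]))
        with pytest.raises(ValueError):
            resolve_isotopologue_overlap(env, reduced, oxidized)


class TestAbundanceTable:
    def test_peptide_only_spectrum_gives_zero_adducts(self, at2):
        from metalpept import abundance_table

        model = speciation_from_system("AT2/pic")
        mass = peptide_composition(at2.residues).monoisotopic_mass()
        dec = Spectrum(np.array([mass]), np.array([1e6]))
        tab = abundance_table({"s": dec}, model.neutral_species(), base_species="AT",
                              envelope=False)
        adducts = tab.data.drop(index="AT")
        assert (adducts.values == 0).all()

    def test_scale_invariance(self, at2):
        from metalpept import abundance_table

        model = speciation_from_system("AT2/pic")
        spectrum, _ = simulate_full_ms(model, seed=2)
        dec = deconvolute(spectrum, z_range=(1, 2))
        doubled = dec.replace(intensity=dec.intensity * 2)
        t1 = abundance_table({"s": dec}, model.neutral_species(), base_species="AT")
        t2 = abundance_table({"s": doubled}, model.neutral_species(), base_species="AT")
        np.testing.assert_allclose(t1.data.values, t2.data.values, rtol=1e-12)

    def test_missing_base_peak_is_error(self, at2):
        from metalpept import abundance_table

        model = speciation_from_system("AT2/pic")
        dec = Spectrum(np.array([500.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            abundance_table({"s": dec}, model.neutral_species(), base_species="AT")


def _map_from_rows(rows, precursor="[M + VO(pic) + H]2+"):
    entries = pd.DataFrame(
        rows, columns=["label", "series", "index", "metalated", "abundance", "major"]
    )
    return FragmentationMap(precursor=precursor, entries=entries, nce_values=(20.0,))


class TestFragmentationMap:
    def test_threshold_is_strict(self, at2):
        """A fragment at exactly 1.0 % is classed minor."""
        frag = AdductIon(base=Fragment("b", 3, at2))
        base = AdductIon(base=Fragment("b", 6, at2))
        sp = Spectrum(
            np.array(sorted([frag.mz(), base.mz()])),
            np.array([1.0, 100.0] if frag.mz() < base.mz() else [100.0, 1.0]),
            ms_level=2,
            nce=25.0,
            precursor="p",
        )
        prec = parse_label("[AT + VO(pic) + H]2+", peptide=at2)
        fmap = fragmentation_map([sp], prec, peptide=at2)
        row = fmap.entries.set_index("label").loc["[b3]+"]
        assert row["abundance"] == pytest.approx(1.0)
        assert not row["major"]

    def test_no_matching_peaks_gives_empty_map(self, at2):
        sp = Spectrum(np.array([9000.0]), np.array([1.0]), ms_level=2, nce=25.0,
                      precursor="p")
        prec = parse_label("[AT + VO(pic) + H]2+", peptide=at2)
        fmap = fragmentation_map([sp], prec, peptide=at2)
        assert len(fmap.entries) == 0

    def test_requires_spectra_in_window(self, at2):
        sp = Spectrum(np.array([100.0]), np.array([1.0]), ms_level=2, nce=5.0,
                      precursor="p")
        prec = parse_label("[AT + VO(pic) + H]2+", peptide=at2)
        with pytest.raises(ValueError):
            fragmentation_map([sp], prec, peptide=at2)


class TestLocalization:
    def test_at2_b6_y4_brackets_his6(self, at2):
        fmap = _map_from_rows(
            [
                ("[b6 + VO - H]2+", "b", 6, True, 10.0, True),
                ("[y4″ + VO - 2H]+", "y", 4, True, 2.0, True),
            ]
        )
        loc = localize_binding(fmap, at2)
        assert loc.intervals == ((5, 6),)
        assert not loc.conflicting
        assert loc.covers(6)

    def test_at1_b9_y4_brackets_his9(self, at1):
        fmap = _map_from_rows(
            [
                ("[b9 + VO - H]2+", "b", 9, True, 10.0, True),
                ("[y4″ + VO - 2H]+", "y", 4, True, 2.0, True),
            ]
        )
        loc = localize_binding(fmap, at1)
        assert loc.intervals == ((7, 9),)
        assert loc.covers(9)

    def test_only_b2_points_to_n_terminus(self, at2):
        fmap = _map_from_rows([("[b2 + VO - 2H]+", "b", 2, True, 1.5, True)])
        loc = localize_binding(fmap, at2)
        assert loc.intervals == ((1, 2),)

    def test_conflicting_constraints_flagged(self, at1):
        fmap = _map_from_rows(
            [
                ("[b6 + VO - H]2+", "b", 6, True, 5.0, True),
                ("[y2″ + VO - 2H]+", "y", 2, True, 5.0, True),
            ]
        )
        loc = localize_binding(fmap, at1)
        assert loc.conflicting
        assert loc.intervals == ((1, 6), (9, 10))

    def test_residue_scores_sum_covering_fragments(self, at2):
        fmap = _map_from_rows(
            [
                ("[b6 + VO - H]2+", "b", 6, True, 10.0, True),
                ("[y4″ + VO - 2H]+", "y", 4, True, 2.0, True),
            ]
        )
        loc = localize_binding(fmap, at2)
        assert loc.residue_scores[6] == pytest.approx(12.0)
        assert loc.residue_scores[1] == pytest.approx(10.0)
        assert loc.residue_scores[8] == pytest.approx(2.0)


class TestStabilityProfile:
    def test_precursor_only_spectrum_survival_one(self, at2):
        prec = parse_label("[AT + VO(pic) + H]2+", peptide=at2)
        sp = Spectrum(np.array([prec.mz()]), np.array([1e6]), ms_level=2, nce=0.0,
                      precursor=prec.label)
        df = nce_stability_profile([sp], prec)
        assert df.loc[0.0, "survival"] == pytest.approx(1.0)

    def test_requires_nce_annotation(self, at2):
        prec = parse_label("[AT + VO(pic) + H]2+", peptide=at2)
        sp = Spectrum(np.array([prec.mz()]), np.array([1e6]), ms_level=2,
                      precursor=prec.label)
        with pytest.raises(ValueError):
            nce_stability_profile([sp], prec)
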