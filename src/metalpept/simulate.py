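"""Seeded generators of full-MS and NCE-resolved MS2 spectra with ground truth.

The full-MS generator emulates the adduct speciation an electrospray
spectrum of a peptide/oxidovanadium incubation shows: the free peptide
as base peak plus [AT + VOL], [AT + VOL2], [AT + VO] and [AT + VO2]
species at prescribed relative abundances, each as an isotope envelope
over charge states 1-2, with ppm-scale mass jitter, multiplicative
intensity noise and a uniform noise floor.  The MS2 generator emulates
HCD energy-resolved fragmentation: logistic precursor survival in NCE
(ligand-dependent presets), ligand-loss and complex-detachment channels,
and backbone a/b/y/z fragments whose metal retention follows the planted
binding residues.  Every spectrum comes with a serializable ground-truth
record; all randomness flows from one integer seed in a documented draw
order (jitter first, then intensity noise, then noise peaks).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .adducts import (
    AdductIon,
    Fragment,
    MetalMoiety,
    VO,
    VO2,
    VOL,
    VOL2,
    neutral_adduct,
    parse_moiety,
)
from .composition import PROTON_MASS, ElementalComposition, HYDROGEN, PeptideSequence
from .spectra import Spectrum

__all__ = [
    "SpeciationModel",
    "FragmentationModel",
    "GroundTruth",
    "AT1",
    "AT2",
    "TABLE_SPECIATIONS",
    "LIGAND_PRESETS",
    "simulate_full_ms",
    "simulate_ms2_series",
    "simulate_isotopologue_mixture",
    "ground_truth",
    "load_ground_truth",
]

AT1 = PeptideSequence("DRVYIHPFHL")
AT2 = PeptideSequence("DRVYIHPF")

#: Deconvoluted-spectrum speciation of each incubation system
#: (% of the free-peptide base peak): [AT + VOL], [AT + VOL2],
#: [AT + VO], [AT + VO2].
TABLE_SPECIATIONS: dict[str, dict[str, float]] = {
    "AT2/dhp": {"VOL": 4.35, "VOL2": 0.11, "VO": 0.60, "VO2": 0.70},
    "AT1/dhp": {"VOL": 4.53, "VOL2": 0.00, "VO": 0.34, "VO2": 0.31},
    "AT2/ma": {"VOL": 4.49, "VOL2": 0.02, "VO": 1.55, "VO2": 0.72},
    "AT1/ma": {"VOL": 2.02, "VOL2": 0.00, "VO": 0.92, "VO2": 0.37},
    "AT2/pic": {"VOL": 2.82, "VOL2": 1.92, "VO": 5.32, "VO2": 0.16},
    "AT1/pic": {"VOL": 3.67, "VOL2": 0.48, "VO": 1.29, "VO2": 0.09},
}

#: Qualitative HCD stability presets per chelator: logistic precursor
#: survival midpoint/steepness (NCE units) and how the non-surviving ion
#: partitions between whole-complex detachment (free peptide) and ligand
#: loss (metal retained).  dhp complexes detach whole at low energy; pic
#: loses its ligands early but keeps [VO] bound through NCE 30.
LIGAND_PRESETS: dict[str, dict[str, float]] = {
    "dhp": {"survival_mid": 18.0, "survival_steep": 3.0, "detach_frac": 0.70},
    "ma": {"survival_mid": 12.0, "survival_steep": 3.0, "detach_frac": 0.35},
    "pic": {"survival_mid": 10.0, "survival_steep": 3.0, "detach_frac": 0.10},
    "none": {"survival_mid": 30.0, "survival_steep": 2.5, "detach_frac": 0.0},
}


def _logistic_survival(nce: float, mid: float, steep: float) -> float:
    return 1.0 / (1.0 + np.exp((nce - mid) / steep))


def _system_peptide(name: str) -> PeptideSequence:
    return AT1 if name.startswith("AT1") else AT2


def speciation_from_system(system: str) -> "SpeciationModel":
    """Preset :class:`SpeciationModel` for an incubation system like ``"AT2/pic"``."""
    if system not in TABLE_SPECIATIONS:
        raise KeyError(f"unknown system {system!r}; choose from {sorted(TABLE_SPECIATIONS)}")
    pep, lig = system.split("/")
    spec = TABLE_SPECIATIONS[system]
    species = (
        (f"VO({lig})", spec["VOL"]),
        (f"VO({lig})2", spec["VOL2"]),
        ("VO", spec["VO"]),
        ("VO2", spec["VO2"]),
    )
    return SpeciationModel(peptide=_system_peptide(system), species=species, system=system)


# --- Full-MS speciation ------------------------------------------------

@dataclass(frozen=True)
class SpeciationModel:
    """Study conditions for one simulated full-MS spectrum.

    ``species`` lists (moiety token, relative abundance in % of the free
    peptide); the free peptide itself is implicit at 100 %.  Charge-state
    weights apply to every species; jitter is Gaussian in ppm; the noise
    floor adds ``noise_peaks`` spurious exponential-intensity peaks.
    """

    peptide: PeptideSequence
    species: tuple[tuple[str, float], ...]
    charge_weights: tuple[tuple[int, float], ...] = ((1, 0.45), (2, 0.55))
    ppm_jitter: float = 2.0
    base_intensity: float = 1.0e6
    intensity_cv: float = 0.01
    noise_peaks: int = 50
    noise_intensity: float = 30.0
    mz_range: tuple[float, float] = (300.0, 1700.0)
    isotopes: bool = True
    iso_threshold: float = 1e-4
    system: str | None = None

    def __post_init__(self):
        for token, pct in self.species:
            if pct < 0:
                raise ValueError(f"negative abundance for species {token!r}")
        total = sum(w for _, w in self.charge_weights)
        if total <= 0:
            raise ValueError("charge weights must sum to a positive number")

    def neutral_species(self) -> dict[str, ElementalComposition]:
        """Label -> neutral composition for the peptide and each adduct."""
        out = {"AT": self.peptide.composition()}
        for token, _ in self.species:
            ion = neutral_adduct(self.peptide, parse_moiety(token))
            out[ion.label] = ion.composition
        return out

    def species_labels(self) -> dict[str, str]:
        """Moiety token -> canonical neutral species label."""
        return {
            token: neutral_adduct(self.peptide, parse_moiety(token)).label
            for token, _ in self.species
        }


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every simulated spectrum."""

    kind: str
    seed: int
    peptide: str
    species_abundances: dict[str, float] = field(default_factory=dict)
    neutral_masses: dict[str, float] = field(default_factory=dict)
    binding_residues: tuple[int, ...] = ()
    oxidation_fractions: dict[str, float] = field(default_factory=dict)
    survival: dict[str, float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["binding_residues"] = list(self.binding_residues)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["binding_residues"] = tuple(d.get("binding_residues", ()))
        return cls(**d)


def ground_truth(record: GroundTruth, path=None) -> str:
    """Serialize a ground-truth record (optionally to ``path``); lossless."""
    text = record.to_json()
    if path is not None:
        Path(path).write_text(text)
    return text


def load_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def _envelope(comp: ElementalComposition, model_iso: bool, threshold: float):
    if model_iso:
        return comp.isotope_pattern(prob_threshold=threshold)
    return [(0.0, 1.0)]


def simulate_full_ms(model: SpeciationModel, seed: int = 0) -> tuple[Spectrum, GroundTruth]:
    """One full-MS spectrum of the modelled speciation, plus its ground truth."""
    rng = np.random.default_rng(seed)
    zw = dict(model.charge_weights)
    norm = sum(zw.values())
    zw = {z: w / norm for z, w in zw.items()}

    peaks_mz, peaks_int = [], []
    truth = GroundTruth(
        kind="full_ms",
        seed=seed,
        peptide=str(model.peptide),
        species_abundances={"AT": 100.0},
    )
    inventory = [("AT", 100.0, model.peptide.composition())]
    for token, pct in model.species:
        ion = neutral_adduct(model.peptide, parse_moiety(token))
        inventory.append((ion.label, pct, ion.composition))
        truth.species_abundances[ion.label] = pct
    for label, pct, comp in inventory:
        truth.neutral_masses[label] = comp.monoisotopic_mass()
        if pct <= 0:
            continue
        pattern = _envelope(comp, model.isotopes, model.iso_threshold)
        mono = comp.monoisotopic_mass()
        for z, w in zw.items():
            for off, p in pattern:
                mz = (mono + off + z * PROTON_MASS) / z
                if not model.mz_range[0] <= mz <= model.mz_range[1]:
                    continue
                jitter = rng.normal(0.0, model.ppm_jitter) * 1e-6
                noise = max(0.0, 1.0 + rng.normal(0.0, model.intensity_cv))
                peaks_mz.append(mz * (1.0 + jitter))
                peaks_int.append(model.base_intensity * pct / 100.0 * w * p * noise)

    if model.noise_peaks:
        noise_mz = rng.uniform(*model.mz_range, size=model.noise_peaks)
        noise_int = rng.exponential(model.noise_intensity, size=model.noise_peaks)
        peaks_mz.extend(noise_mz.tolist())
        peaks_int.extend(noise_int.tolist())

    spectrum = Spectrum(
        np.array(peaks_mz),
        np.array(peaks_int),
        ms_level=1,
        metadata={"seed": seed, "system": model.system or "custom", "simulated": True},
    )
    return spectrum, truth


# --- MS2 energy series -------------------------------------------------

@dataclass(frozen=True)
class FragmentationModel:
    """Study conditions for one simulated HCD energy series.

    The metal-retention rule is structural: a backbone fragment retains
    the (post-ligand-loss) metal moiety exactly when it contains a
    planted binding residue; when the binding residues fall on both
    sides of a cleavage, the metal splits in proportion to the count on
    each side.  Oxidation channels (V(III)/V(IV)/V(V)) receive fixed
    weights, with z-type fragments biased to the reduced V(III) channel.
    """

    precursor: AdductIon
    binding_residues: tuple[int, ...]
    nce_grid: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)
    survival_mid: float | None = None
    survival_steep: float | None = None
    detach_frac: float | None = None
    fragment_mid: float = 28.0
    fragment_steep: float = 2.5
    series_weights: tuple[tuple[str, float], ...] = (
        ("a", 0.25), ("b", 0.35), ("y", 0.30), ("z", 0.10)
    )
    os_weights: tuple[tuple[int, float], ...] = ((4, 0.85), (3, 0.10), (5, 0.05))
    os_weights_z_series: tuple[tuple[int, float], ...] = ((3, 0.85), (4, 0.15))
    cleavage_propensities: tuple[float, ...] | None = None  # per site, len n-1
    fragment_metal: str = "VO"  # moiety retained by metalated fragments
    ppm_jitter: float = 2.0
    intensity_cv: float = 0.01
    total_intensity: float = 1.0e6
    noise_peaks: int = 20
    noise_intensity: float = 20.0
    isotopes: bool = False
    iso_threshold: float = 1e-3

    @property
    def peptide(self) -> PeptideSequence:
        base = self.precursor.base
        return base if isinstance(base, PeptideSequence) else base.parent

    @property
    def ligand_name(self) -> str:
        ligs = {l.name for m in self.precursor.moieties for l in m.ligands}
        return next(iter(ligs)) if ligs else "none"

    def _preset(self, key: str) -> float:
        value = getattr(self, {"survival_mid": "survival_mid",
                               "survival_steep": "survival_steep",
                               "detach_frac": "detach_frac"}[key])
        if value is not None:
            return value
        preset = LIGAND_PRESETS.get(self.ligand_name, LIGAND_PRESETS["none"])
        return preset[key]

    def survival(self, nce: float) -> float:
        return _logistic_survival(nce, self._preset("survival_mid"),
                                  self._preset("survival_steep"))

    def fragmentation_onset(self, nce: float) -> float:
        return 1.0 - _logistic_survival(nce, self.fragment_mid, self.fragment_steep)


def _metal_share(frag: Fragment, binding: tuple[int, ...]) -> float:
    """Fraction of the metal retained by ``frag`` under the retention rule."""
    if not binding:
        return 0.0
    lo, hi = frag.span()
    inside = sum(1 for r in binding if lo <= r <= hi)
    return inside / len(binding)


def _fragment_ion(frag: Fragment, moiety: MetalMoiety | None, z: int, os_state: int | None):
    """Build the concrete ion for one simulated fragment channel.

    For metalated fragments the proton adjustment follows from the
    charge-balance identity at the requested oxidation state; bare
    fragments carry protons only (z-1 beyond the canonical one).
    """
    if moiety is None:
        return AdductIon(base=frag, charge=z, protons_added=z - 1)
    # net protons = z - OS + 2 n_oxo + n_lig; canonical proton counts as +1
    net = z - os_state + 2 * moiety.n_oxo + moiety.n_ligands
    delta = net - 1
    if delta >= 0:
        return AdductIon(base=frag, moieties=(moiety,), charge=z, protons_added=delta)
    return AdductIon(base=frag, moieties=(moiety,), charge=z, protons_removed=-delta)


def simulate_ms2_series(
    model: FragmentationModel, seed: int = 0
) -> tuple[list[Spectrum], GroundTruth]:
    """HCD spectra over the NCE grid for one precursor, plus ground truth."""
    rng = np.random.default_rng(seed)
    pep = model.peptide
    n = len(pep)
    precursor = model.precursor
    prec_label = precursor.label
    props = (
        np.asarray(model.cleavage_propensities, dtype=float)
        if model.cleavage_propensities is not None
        else np.ones(n - 1)
    )
    if props.size != n - 1 or np.any(props < 0) or props.sum() == 0:
        raise ValueError("cleavage propensities must be n-1 non-negative numbers")
    props = props / props.sum()
    series_w = dict(model.series_weights)
    detach = model._preset("detach_frac")

    truth = GroundTruth(
        kind="ms2_series",
        seed=seed,
        peptide=str(pep),
        binding_residues=tuple(sorted(model.binding_residues)),
        extras={"precursor": prec_label, "nce_grid": list(model.nce_grid)},
    )
    for os_state, w in model.os_weights:
        truth.oxidation_fractions[str(os_state)] = w

    metal_moiety = parse_moiety(model.fragment_metal) if precursor.n_v else None
    spectra = []
    for nce in model.nce_grid:
        channels: dict[AdductIon, float] = {}

        def add(ion: AdductIon, amount: float):
            if amount > 0:
                channels[ion] = channels.get(ion, 0.0) + amount

        s = model.survival(nce)
        truth.survival[f"{nce:g}"] = s
        add(precursor, s)

        dissociated = 1.0 - s
        f_frag = model.fragmentation_onset(nce)
        backbone = dissociated * f_frag
        residual = dissociated - backbone

        # whole-complex detachment -> free (protonated) peptide
        for z, w in ((1, 0.4), (2, 0.6)):
            add(
                AdductIon(base=pep, charge=z, protons_added=z, base_symbol="M"),
                residual * detach * w,
            )
        # ligand loss -> intact peptide keeping [VO] (V(IV))
        if precursor.n_v:
            for z, w in ((1, 0.4), (2, 0.6)):
                net = z - 4 + 2  # OS IV, one oxo, no ligand
                ion = (
                    AdductIon(base=pep, moieties=(VO(),), charge=z,
                              protons_added=net, base_symbol="M")
                    if net >= 0
                    else AdductIon(base=pep, moieties=(VO(),), charge=z,
                                   protons_removed=-net, base_symbol="M")
                )
                add(ion, residual * (1.0 - detach) * w)
        else:
            for z, w in ((1, 0.4), (2, 0.6)):
                add(
                    AdductIon(base=pep, charge=z, protons_added=z, base_symbol="M"),
                    residual * (1.0 - detach) * w,
                )

        # backbone fragments
        for site in range(1, n):
            site_w = backbone * props[site - 1]
            for series, sw in series_w.items():
                idx = site if series in ("a", "b") else n - site
                if idx < 1 or idx >= n:
                    continue
                frag = Fragment(series, idx, pep)
                amount = site_w * sw
                share = _metal_share(frag, truth.binding_residues) if metal_moiety else 0.0
                # charge partition: larger fragments hold 2+ more readily
                zw = ((1, 0.35), (2, 0.65)) if idx >= 6 else ((1, 0.9), (2, 0.1))
                for z, w in zw:
                    plain = amount * (1.0 - share) * w
                    add(_fragment_ion(frag, None, z, None), plain)
                    if share > 0:
                        os_w = (
                            model.os_weights_z_series
                            if series == "z"
                            else model.os_weights
                        )
                        for os_state, ow in os_w:
                            add(
                                _fragment_ion(frag, metal_moiety, z, os_state),
                                amount * share * w * ow,
                            )

        mz_list, int_list = [], []
        for ion, amount in channels.items():
            pattern = _envelope(ion.composition, model.isotopes, model.iso_threshold)
            base_mz = ion.mz()
            for off, p in pattern:
                jitter = rng.normal(0.0, model.ppm_jitter) * 1e-6
                noise = max(0.0, 1.0 + rng.normal(0.0, model.intensity_cv))
                mz_list.append((base_mz + off / ion.charge) * (1.0 + jitter))
                int_list.append(model.total_intensity * amount * p * noise)
        if model.noise_peaks:
            lo, hi = 150.0, precursor.mz() + 100.0
            mz_list.extend(rng.uniform(lo, hi, size=model.noise_peaks).tolist())
            int_list.extend(
                rng.exponential(model.noise_intensity, size=model.noise_peaks).tolist()
            )
        spectra.append(
            Spectrum(
                np.array(mz_list),
                np.array(int_list),
                ms_level=2,
                nce=float(nce),
                precursor=prec_label,
                isolation_window=5.0,
                metadata={"seed": seed, "simulated": True,
                          "pepmass": precursor.mz(),
                          "precursor_charge": precursor.charge,
                          "title": f"{prec_label} NCE {nce:g}"},
            )
        )
    return spectra, truth


# --- Redox envelope mixtures -------------------------------------------

def simulate_isotopologue_mixture(
    form_reduced: AdductIon,
    form_oxidized: AdductIon,
    fraction_reduced: float,
    total_intensity: float = 1.0e5,
    noise_cv: float = 0.01,
    ppm_jitter: float = 2.0,
    prob_threshold: float = 1e-4,
    seed: int = 0,
) -> tuple[Spectrum, GroundTruth]:
    """Observed peak cluster of two forms one hydrogen apart.

    Emulates the overlapping isotope envelopes of a reduced
    [.. + V(IV)OL + H] and oxidized [.. + V(V)OL] precursor pair at a
    planted mixing fraction, with multiplicative intensity noise and ppm
    jitter.  Peaks closer than 0.02/z Da merge, as they would in a
    centroided spectrum.
    """
    if not 0.0 <= fraction_reduced <= 1.0:
        raise ValueError("fraction_reduced must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cluster: dict[int, list[float]] = {}
    for form, frac in ((form_reduced, fraction_reduced),
                       (form_oxidized, 1.0 - fraction_reduced)):
        if frac <= 0:
            continue
        z = form.charge
        base = form.mz()
        for off, p in form.composition.isotope_pattern(prob_threshold=prob_threshold):
            mz = base + off / z
            key = round(mz / (0.02 / z))
            cluster.setdefault(key, [0.0, 0.0])
            entry = cluster[key]
            amt = total_intensity * frac * p
            entry[0] += mz * amt
            entry[1] += amt
    mz_list, int_list = [], []
    for wsum, amt in cluster.values():
        jitter = rng.normal(0.0, ppm_jitter) * 1e-6
        noise = max(0.0, 1.0 + rng.normal(0.0, noise_cv))
        mz_list.append((wsum / amt) * (1.0 + jitter))
        int_list.append(amt * noise)
    spectrum = Spectrum(
        np.array(mz_list),
        np.array(int_list),
        ms_level=1,
        metadata={"seed": seed, "simulated": True},
    )
    truth = GroundTruth(
        kind="redox_mixture",
        seed=seed,
        peptide="",
        oxidation_fractions={
            "reduced": fraction_reduced,
            "oxidized": 1.0 - fraction_reduced,
        },
        extras={"form_reduced": form_reduced.label,
                "form_oxidized": form_oxidized.label},
    )
    return spectrum, truth
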