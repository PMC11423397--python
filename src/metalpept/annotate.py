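"""Annotation pipeline: deconvolution, peak matching, V(IV)/V(V) envelope
resolution, abundance tables, fragmentation maps and binding-site
localization.

The matching semantics are deliberately simple and transparent: every
observed peak is assigned to the candidate ion with the smallest |ppm|
error inside a configurable tolerance (default 10 ppm, Orbitrap-class
accuracy), with ties broken first by fewer proton adjustments, then by
the oxidation state closest to +IV.  Species one hydrogen apart — the
reduced [.. + V(IV)OL + H] and oxidized [.. + V(V)OL] forms of the same
adduct — overlap within their isotope envelopes and are separated by a
non-negative least-squares mixture fit of the two theoretical envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .adducts import AdductIon, Fragment, MetalMoiety, VO, VOL, enumerate_candidates, enumerate_fragments
from .composition import PROTON_MASS, ElementalComposition, PeptideSequence
from .spectra import AbundanceTable, Spectrum, normalize_to_base_peak

__all__ = [
    "Assignment",
    "FragmentationMap",
    "LocalizationResult",
    "deconvolute",
    "match_peaks",
    "resolve_isotopologue_overlap",
    "abundance_table",
    "fragmentation_map",
    "localize_binding",
    "nce_stability_profile",
]

DEFAULT_PPM_TOL = 10.0
#: Mean spacing between adjacent isotopologues of light-element ions.
ISOTOPE_SPACING = 1.00335


def _ppm(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


# --- Charge-state deconvolution ----------------------------------------

def _infer_charges(mz: np.ndarray, intensity: np.ndarray, z_range, ppm_tol: float) -> np.ndarray:
    """Greedy per-peak charge inference.

    Isotope-envelope spacing (1.00335/z between neighbours) is the
    primary evidence, scanned from high to low z so that a z=2 envelope
    is not mistaken for two interleaved z=1 chains.  Isolated peaks fall
    back to cross-charge corroboration (two interpretations agreeing on
    the same neutral mass), then to the smallest allowed charge.
    """
    n = mz.size
    charges = np.zeros(n, dtype=int)
    spacing_tol = np.maximum(0.01, 2 * ppm_tol * mz * 1e-6)
    for z in sorted(set(z_range), reverse=True):
        step = ISOTOPE_SPACING / z
        i = 0
        while i < n:
            if charges[i]:
                i += 1
                continue
            chain = [i]
            j = i
            while True:
                target = mz[j] + step
                nxt = np.searchsorted(mz, target)
                best = -1
                for k in (nxt - 1, nxt):
                    if 0 <= k < n and not charges[k] and abs(mz[k] - target) <= spacing_tol[j]:
                        if best < 0 or abs(mz[k] - target) < abs(mz[best] - target):
                            best = k
                if best < 0:
                    break
                chain.append(best)
                j = best
            if len(chain) >= 2:
                charges[chain] = z
            i += 1
    # cross-charge corroboration for leftover singletons
    zs = sorted(set(z_range))
    known_masses = [
        (z * m - z * PROTON_MASS) for m, z in zip(mz[charges > 0], charges[charges > 0])
    ]
    known_masses = np.array(sorted(known_masses)) if known_masses else np.empty(0)
    unresolved = np.flatnonzero(charges == 0)
    hypotheses = {
        i: {z: z * mz[i] - z * PROTON_MASS for z in zs} for i in unresolved
    }
    for i in unresolved:
        best_z = 0
        for z, m in hypotheses[i].items():
            tol = m * ppm_tol * 1e-6
            if known_masses.size:
                k = np.searchsorted(known_masses, m)
                for kk in (k - 1, k):
                    if 0 <= kk < known_masses.size and abs(known_masses[kk] - m) <= tol:
                        best_z = z
            if not best_z:
                for j in unresolved:
                    if j == i:
                        continue
                    for z2, m2 in hypotheses[j].items():
                        if (z2, round(m2, 6)) != (z, round(m, 6)) and abs(m2 - m) <= tol:
                            best_z = z
            if best_z:
                break
        charges[i] = best_z or zs[0]
    return charges


def deconvolute(
    spectrum: Spectrum,
    z_range=(1, 2, 3, 4),
    ppm_tol: float = DEFAULT_PPM_TOL,
) -> Spectrum:
    """Transform a full-MS spectrum to neutral-mass space.

    Each peak's neutral mass is M = z*(m/z) - z*m_proton; peaks agreeing
    on M within ``ppm_tol`` are clustered (intensity-weighted mean mass,
    summed intensity).  Per-peak charges are honoured when present,
    otherwise inferred greedily (see :func:`_infer_charges`).
    """
    if spectrum.ms_level != 1:
        raise ValueError("deconvolution expects an MS1 spectrum")
    if not len(spectrum):
        return spectrum.replace(metadata={**spectrum.metadata, "deconvoluted": True})
    if spectrum.charges is not None and np.all(spectrum.charges > 0):
        charges = spectrum.charges
    else:
        charges = _infer_charges(spectrum.mz, spectrum.intensity, z_range, ppm_tol)
    masses = charges * spectrum.mz - charges * PROTON_MASS
    order = np.argsort(masses, kind="stable")
    masses, inten = masses[order], spectrum.intensity[order]
    out_m, out_i = [], []
    cur_m, cur_i = masses[0], inten[0]
    for m, w in zip(masses[1:], inten[1:]):
        if abs(m - cur_m) <= cur_m * ppm_tol * 1e-6:
            cur_m = (cur_m * cur_i + m * w) / (cur_i + w)
            cur_i += w
        else:
            out_m.append(cur_m)
            out_i.append(cur_i)
            cur_m, cur_i = m, w
    out_m.append(cur_m)
    out_i.append(cur_i)
    return Spectrum(
        np.array(out_m),
        np.array(out_i),
        ms_level=1,
        metadata={**spectrum.metadata, "deconvoluted": True},
    )


# --- Peak matching -----------------------------------------------------

@dataclass(frozen=True)
class Assignment:
    """One observed peak explained by one candidate ion."""

    ion: AdductIon
    peak_index: int
    mz: float
    intensity: float
    ppm_error: float
    nce: float | None = None
    isotopologue: int = 0  # 0 = monoisotopic peak


def _tie_key(ion: AdductIon) -> tuple:
    adjustments = ion.protons_added + ion.protons_removed
    try:
        os_dev = abs(ion.oxidation_state - 4)
    except ValueError:
        os_dev = 0
    return (adjustments, os_dev)


def match_peaks(
    candidates: list[AdductIon],
    spectrum: Spectrum,
    ppm_tol: float = DEFAULT_PPM_TOL,
    isotopologues: int = 2,
) -> list[Assignment]:
    """Assign each peak to the candidate with the smallest |ppm| error.

    Besides the monoisotopic peak, each candidate may claim up to
    ``isotopologues`` heavier isotopologue peaks (at +k*1.00335/z);
    monoisotopic interpretations win over isotopologue ones at equal
    |ppm|.  Unmatched peaks are simply left out.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    theo: list[tuple[float, int, AdductIon]] = []
    for ion in candidates:
        m0 = ion.mz()
        for k in range(isotopologues + 1):
            theo.append((m0 + k * ISOTOPE_SPACING / ion.charge, k, ion))
    theo.sort(key=lambda t: t[0])
    theo_mz = np.array([t[0] for t in theo])

    out = []
    for idx in range(len(spectrum)):
        obs = spectrum.mz[idx]
        lo = np.searchsorted(theo_mz, obs * (1 - ppm_tol * 1e-6))
        hi = np.searchsorted(theo_mz, obs * (1 + ppm_tol * 1e-6), side="right")
        best = None
        for t in range(lo, hi):
            tm, k, ion = theo[t]
            err = _ppm(obs, tm)
            # monoisotopic interpretations outrank isotopologue claims:
            # a +1 isotopologue of an ion one H lighter sits only ~2 mDa
            # from a mono peak and must not steal it
            key = (k, round(abs(err), 3)) + _tie_key(ion)
            if best is None or key < best[0]:
                best = (key, err, k, ion)
        if best is not None:
            _, err, k, ion = best
            out.append(
                Assignment(
                    ion=ion,
                    peak_index=idx,
                    mz=obs,
                    intensity=float(spectrum.intensity[idx]),
                    ppm_error=err,
                    nce=spectrum.nce,
                    isotopologue=k,
                )
            )
    return out


# --- V(IV)/V(V) envelope separation ------------------------------------

def resolve_isotopologue_overlap(
    envelope: Spectrum,
    form_a: AdductIon,
    form_b: AdductIon,
    mz_tol: float = 0.02,
    prob_threshold: float = 1e-4,
) -> tuple[float, float, float]:
    """Fractions of two forms one hydrogen apart in an observed cluster.

    ``form_a`` is the reduced (+1 H) form, ``form_b`` the oxidized one.
    The two theoretical isotope envelopes (at each form's own charge) are
    fitted to the observed peaks by non-negative least squares; returned
    fractions are normalized to sum to 1, alongside the relative fit
    residual ||Ax - y|| / ||y||.
    """
    comp_a, comp_b = form_a.composition, form_b.composition
    try:
        diff = comp_a - comp_b
    except Exception:
        raise ValueError("form_a must contain form_b plus exactly one H")
    if dict(diff.counts) != {"H": 1}:
        raise ValueError("the two forms must differ by exactly one hydrogen")
    if not len(envelope) or float(np.sum(envelope.intensity)) == 0.0:
        raise ValueError("degenerate (all-zero) envelope cluster")

    obs_mz = envelope.mz
    y = envelope.intensity.astype(float)
    design = np.zeros((obs_mz.size, 2))
    for col, form in enumerate((form_a, form_b)):
        z = form.charge
        base = form.mz()
        for off, p in form.composition.isotope_pattern(prob_threshold=prob_threshold):
            target = base + off / z
            i = int(np.argmin(np.abs(obs_mz - target)))
            if abs(obs_mz[i] - target) <= mz_tol:
                design[i, col] += p
    coef, _ = nnls(design, y)
    total = coef.sum()
    if total == 0:
        raise ValueError("neither form explains any observed peak")
    resid = float(np.linalg.norm(design @ coef - y) / np.linalg.norm(y))
    return float(coef[0] / total), float(coef[1] / total), resid


# --- Abundance tables (full MS) ----------------------------------------

def _species_intensity(
    deconv: Spectrum,
    composition: ElementalComposition,
    ppm_tol: float,
    envelope: bool,
) -> float:
    """Summed deconvoluted intensity attributable to one neutral species."""
    mono = composition.monoisotopic_mass()
    targets = (
        [(off, p) for off, p in composition.isotope_pattern(prob_threshold=1e-4)]
        if envelope
        else [(0.0, 1.0)]
    )
    total = 0.0
    for off, _ in targets:
        m = mono + off
        tol = m * ppm_tol * 1e-6
        lo = np.searchsorted(deconv.mz, m - tol)
        hi = np.searchsorted(deconv.mz, m + tol, side="right")
        if hi > lo:
            total += float(np.sum(deconv.intensity[lo:hi]))
    return total


def abundance_table(
    deconvoluted: dict[str, Spectrum],
    species: dict[str, ElementalComposition | AdductIon],
    base_species: str,
    ppm_tol: float = DEFAULT_PPM_TOL,
    envelope: bool = True,
) -> AbundanceTable:
    """Per-system relative abundances (% of the base-peak species).

    ``species`` maps label -> neutral composition (or a neutral
    :class:`AdductIon`); with ``envelope`` on, the whole isotope envelope
    of each species is summed so that ratios are not biased by
    composition-dependent monoisotopic fractions.
    """
    if base_species not in species:
        raise ValueError(f"base species {base_species!r} missing from the inventory")

    def comp_of(s) -> ElementalComposition:
        return s.composition if isinstance(s, AdductIon) else s

    values = {}
    for system, spec in deconvoluted.items():
        base_i = _species_intensity(spec, comp_of(species[base_species]), ppm_tol, envelope)
        if base_i <= 0:
            raise ValueError(f"base-peak species not found in system {system!r}")
        col = {}
        for label, s in species.items():
            col[label] = 100.0 * _species_intensity(spec, comp_of(s), ppm_tol, envelope) / base_i
        values[system] = col
    df = pd.DataFrame(values).loc[list(species)]
    df.loc[base_species] = 100.0
    return AbundanceTable(df, base_species=base_species)


# --- Fragmentation maps (MS2) ------------------------------------------

@dataclass
class FragmentationMap:
    """Per-fragment relative abundances (% of MS2 base peak), averaged
    over an NCE window, for one precursor.

    ``entries`` rows: label, series, index, metalated, abundance, major
    (strictly above the display threshold, default 1.0 %).
    """

    precursor: str
    entries: pd.DataFrame
    nce_values: tuple[float, ...]
    threshold: float = 1.0

    def metalated(self) -> pd.DataFrame:
        return self.entries[self.entries["metalated"]]

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.entries.nlargest(n, "abundance")


def default_fragment_candidates(
    peptide: PeptideSequence,
    precursor: AdductIon,
    q_range=(0, 1, 2, 3),
) -> list[AdductIon]:
    """Candidate fragment ions for MS2 annotation of one precursor.

    Fragments may be bare (proton charge carriers only) or carry a
    sub-moiety of the precursor's metal unit: [VO] after full ligand
    loss, or [VOL] when the precursor retained a chelator.
    """
    fragments = enumerate_fragments(peptide)
    moieties: list[MetalMoiety | None] = [None]
    if precursor.n_v == 1:
        moieties.append(VO())
        for lig in {l.name for m in precursor.moieties for l in m.ligands}:
            moieties.append(VOL(lig))
    zs = tuple(range(1, max(2, precursor.charge) + 1))
    return enumerate_candidates(
        fragments, moieties=moieties, z_range=zs, q_range=q_range, p_range=(0, 1)
    )


def fragmentation_map(
    spectra: list[Spectrum],
    precursor: AdductIon,
    peptide: PeptideSequence | None = None,
    candidates: list[AdductIon] | None = None,
    nce_window: tuple[float, float] = (20.0, 35.0),
    ppm_tol: float = DEFAULT_PPM_TOL,
    threshold: float = 1.0,
) -> FragmentationMap:
    """Average fragment relative abundances over MS2 spectra in the NCE window.

    Each spectrum is normalized to its own base peak (in %); per-ion
    percentages (summed over claimed isotopologue peaks) are then
    averaged across the spectra of the window.  Entries strictly above
    ``threshold`` % are classed major, the rest minor.
    """
    if peptide is None:
        base = precursor.base
        if isinstance(base, Fragment):
            raise ValueError("precursor of a fragmentation map must be a whole peptide")
        peptide = base
    selected = [
        s for s in spectra
        if s.ms_level == 2 and s.nce is not None and nce_window[0] <= s.nce <= nce_window[1]
    ]
    if not selected:
        raise ValueError(f"no MS2 spectra inside the NCE window {nce_window}")
    if candidates is None:
        candidates = default_fragment_candidates(peptide, precursor)

    per_ion: dict[str, list[float]] = {}
    meta: dict[str, tuple] = {}
    for spec in selected:
        norm = normalize_to_base_peak(spec)
        totals: dict[str, float] = {}
        for a in match_peaks(candidates, norm, ppm_tol=ppm_tol):
            if not isinstance(a.ion.base, Fragment):
                continue
            label = a.ion.label
            totals[label] = totals.get(label, 0.0) + a.intensity
            meta[label] = (
                a.ion.base.series,
                a.ion.base.index,
                a.ion.n_v > 0,
            )
        for label, val in totals.items():
            per_ion.setdefault(label, []).append(val)

    rows = []
    n_spec = len(selected)
    for label, vals in per_ion.items():
        series, index, metalated = meta[label]
        abundance = sum(vals) / n_spec  # spectra lacking the ion contribute 0
        rows.append(
            {
                "label": label,
                "series": series,
                "index": index,
                "metalated": metalated,
                "abundance": abundance,
                "major": abundance > threshold,
            }
        )
    entries = pd.DataFrame(
        rows, columns=["label", "series", "index", "metalated", "abundance", "major"]
    )
    if len(entries):
        entries = entries.sort_values("abundance", ascending=False).reset_index(drop=True)
    return FragmentationMap(
        precursor=precursor.label,
        entries=entries,
        nce_values=tuple(sorted({float(s.nce) for s in selected})),
        threshold=threshold,
    )


# --- Binding-site localization -----------------------------------------

@dataclass
class LocalizationResult:
    """Residue interval(s) consistent with the metalated fragments.

    1-based inclusive intervals.  With contradictory evidence (e.g. two
    binding sites) the N- and C-terminal constraint intervals are both
    reported and ``conflicting`` is set.
    """

    intervals: tuple[tuple[int, int], ...]
    residue_scores: dict[int, float]
    conflicting: bool = False

    def covers(self, residue: int) -> bool:
        return any(lo <= residue <= hi for lo, hi in self.intervals)


def localize_binding(
    fmap: FragmentationMap,
    peptide: PeptideSequence,
    min_abundance: float = 0.0,
) -> LocalizationResult:
    """Intersect the residue constraints implied by metalated fragments.

    A metalated N-terminal fragment a_i/b_i places the site within
    residues 1..i; a metalated C-terminal fragment y_j/z_j within
    residues (n-j+1)..n.  Per-residue evidence is the summed relative
    abundance of metalated fragments covering the residue.
    """
    n = len(peptide)
    nt_hi, ct_lo = n, 1
    scores = {r: 0.0 for r in range(1, n + 1)}
    any_evidence = False
    for _, row in fmap.metalated().iterrows():
        if row["abundance"] <= min_abundance:
            continue
        any_evidence = True
        i = int(row["index"])
        if row["series"] in ("a", "b"):
            lo, hi = 1, i
            nt_hi = min(nt_hi, i)
        else:
            lo, hi = n - i + 1, n
            ct_lo = max(ct_lo, lo)
        for r in range(lo, hi + 1):
            scores[r] += float(row["abundance"])
    if not any_evidence:
        return LocalizationResult(intervals=(), residue_scores=scores)
    if ct_lo <= nt_hi:
        return LocalizationResult(intervals=((ct_lo, nt_hi),), residue_scores=scores)
    # contradictory constraints: report both candidate sites
    return LocalizationResult(
        intervals=((1, nt_hi), (ct_lo, n)) if nt_hi >= 1 else ((ct_lo, n),),
        residue_scores=scores,
        conflicting=True,
    )


# --- NCE stability profiles --------------------------------------------

def nce_stability_profile(
    spectra: list[Spectrum],
    precursor: AdductIon,
    candidates: list[AdductIon] | None = None,
    peptide: PeptideSequence | None = None,
    ppm_tol: float = DEFAULT_PPM_TOL,
    top_channels: int = 4,
) -> pd.DataFrame:
    """Precursor survival and leading product channels per NCE.

    Survival = precursor intensity / total assigned intensity in each
    spectrum.  The returned frame is indexed by NCE with a ``survival``
    column, one column per leading product channel, and a ``monotone``
    attribute in ``df.attrs`` reporting whether survival decreases with
    NCE.
    """
    if peptide is None:
        base = precursor.base
        peptide = base if isinstance(base, PeptideSequence) else base.parent
    if candidates is None:
        candidates = _precursor_channel_candidates(peptide, precursor)
    selected = sorted(
        (s for s in spectra if s.ms_level == 2 and s.nce is not None),
        key=lambda s: s.nce,
    )
    if not selected:
        raise ValueError("no NCE-annotated MS2 spectra")

    prec_label = precursor.label
    rows: dict[float, dict[str, float]] = {}
    for spec in selected:
        totals: dict[str, float] = {}
        for a in match_peaks(candidates, spec, ppm_tol=ppm_tol):
            totals[a.ion.label] = totals.get(a.ion.label, 0.0) + a.intensity
        total = sum(totals.values())
        row = {"survival": (totals.get(prec_label, 0.0) / total) if total else 0.0}
        for label, val in totals.items():
            if label != prec_label:
                row[label] = val / total if total else 0.0
        rows[float(spec.nce)] = row

    df = pd.DataFrame(rows).T.fillna(0.0).sort_index()
    channel_cols = [c for c in df.columns if c != "survival"]
    keep = (
        df[channel_cols].sum().sort_values(ascending=False).head(top_channels).index.tolist()
        if channel_cols
        else []
    )
    df = df[["survival"] + keep]
    surv = df["survival"].values
    df.attrs["monotone_decreasing"] = bool(np.all(np.diff(surv) <= 1e-9))
    return df


def _precursor_channel_candidates(
    peptide: PeptideSequence, precursor: AdductIon
) -> list[AdductIon]:
    """Precursor itself, ligand-loss species, free peptide and free complex."""
    out = [precursor]
    zs = tuple(range(1, precursor.charge + 1))
    moieties: list[MetalMoiety | None] = [None]
    if precursor.n_v == 1:
        m = precursor.moiety
        moieties.append(VO())
        if m.n_oxo == 2:
            moieties.append(MetalMoiety(1, 2, ()))
        for lig in {l.name for l in m.ligands}:
            moieties.append(VOL(lig))
            if sum(1 for l in m.ligands if l.name == lig) >= 2:
                from .adducts import VOL2

                moieties.append(VOL2(lig))
    out.extend(
        enumerate_candidates(
            peptide, moieties=moieties, z_range=zs, q_range=(0, 1, 2, 3), p_range=(0, 1, 2)
        )
    )
    # fragments (with and without metal) for the high-NCE regime
    out.extend(default_fragment_candidates(peptide, precursor))
    # dedupe by (composition, charge), keep first (the precursor wins)
    seen, dedup = set(), []
    for ion in out:
        key = (ion.composition, ion.charge)
        if key not in seen:
            seen.add(key)
            dedup.append(ion)
    return dedup
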