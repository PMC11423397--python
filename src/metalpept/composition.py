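"""Elemental-composition algebra, peptide chemistry and isotope patterns.

Everything downstream — adduct enumeration, deconvolution, envelope
fitting — runs on :class:`ElementalComposition`, a multiset of
element → count.  Masses and isotope abundances come from the NIST table
bundled with pyteomics; amino-acid residue compositions come from the
same package.  Monoisotopic masses are used throughout the matching code
(high-resolution Orbitrap-class data); average masses are exposed but
never used for matching.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "CompositionError",
    "ElementalComposition",
    "PeptideSequence",
    "parse_formula",
    "combine",
    "peptide_composition",
    "monoisotopic_mass",
    "average_mass",
    "mz_of",
    "isotope_pattern",
]

#: Default element → isotope table, ``{element: {isotope: (mass, abundance)}}``
#: with key 0 holding the principal (most abundant) isotope.
DEFAULT_MASS_TABLE: Mapping = _pmass.nist_mass

ELECTRON_MASS: float = _pmass.nist_mass["e-"][0][0]
#: Mass of H minus the electron; charge carrier in positive-mode ESI.
PROTON_MASS: float = _pmass.nist_mass["H"][0][0] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class CompositionError(ValueError):
    """Raised on unknown elements or negative counts after subtraction."""


def _monoisotopic_element_mass(element: str, table: Mapping) -> float:
    try:
        return table[element][0][0]
    except KeyError:
        raise CompositionError(f"unknown element symbol: {element!r}") from None


@dataclass(frozen=True)
class ElementalComposition(Mapping):
    """Immutable multiset of element symbol → non-negative count.

    Supports ``+``, ``-`` (raising :class:`CompositionError` on underflow)
    and ``*`` by a non-negative integer.  Zero counts are dropped so that
    equal compositions compare equal.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for el, n in dict(self.counts).items():
            if not isinstance(n, int):
                raise CompositionError(f"count for {el!r} must be an integer, got {n!r}")
            if n < 0:
                raise CompositionError(f"negative count for {el!r}: {n}")
            if n:
                clean[str(el)] = n
        object.__setattr__(self, "counts", clean)

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self):
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    # Algebra ----------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise CompositionError(
                    f"composition underflow: cannot remove {n} x {el} "
                    f"from {self.formula() or '{}'}"
                )
            merged[el] = left
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 0:
            raise CompositionError(f"multiplier must be a non-negative integer, got {k!r}")
        return ElementalComposition({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def contains(self, other: "ElementalComposition") -> bool:
        return all(self[el] >= n for el, n in other.counts.items())

    # Masses -----------------------------------------------------------
    def monoisotopic_mass(self, table: Mapping = DEFAULT_MASS_TABLE) -> float:
        return sum(n * _monoisotopic_element_mass(el, table) for el, n in self.counts.items())

    def average_mass(self, table: Mapping = DEFAULT_MASS_TABLE) -> float:
        total = 0.0
        for el, n in self.counts.items():
            if el not in table:
                raise CompositionError(f"unknown element symbol: {el!r}")
            iso = [(m, a) for k, (m, a) in table[el].items() if k != 0 and a > 0]
            if not iso:  # abundance data missing -> fall back to principal isotope
                total += n * table[el][0][0]
                continue
            norm = sum(a for _, a in iso)
            total += n * sum(m * a for m, a in iso) / norm
        return total

    def mz(self, charge: int, electron_correction: bool = True,
           table: Mapping = DEFAULT_MASS_TABLE) -> float:
        """m/z of this composition carrying ``charge`` positive charges.

        The composition must already include the charge-carrying protons
        (as H atoms); with the electron correction on, ``charge``
        electron masses are subtracted before dividing.
        """
        if charge < 1:
            raise ValueError(f"charge must be a positive integer, got {charge}")
        m = self.monoisotopic_mass(table)
        if electron_correction:
            m -= charge * ELECTRON_MASS
        return m / charge

    # Isotopes ---------------------------------------------------------
    def isotope_pattern(self, prob_threshold: float = 1e-4, merge_tol: float = 0.05,
                        table: Mapping = DEFAULT_MASS_TABLE) -> list[tuple[float, float]]:
        """Aggregated isotopologue distribution as (mass offset, intensity).

        Offsets are relative to the monoisotopic mass; intensities are
        renormalized to sum to 1 after pruning peaks below
        ``prob_threshold``.  Peaks closer than ``merge_tol`` Da are merged
        (abundance-weighted mean mass) — a unit-nominal-spacing model
        adequate for resolving species one hydrogen apart, not for fine
        structure.
        """
        if not 0 < prob_threshold < 1:
            raise ValueError("prob_threshold must be in (0, 1)")
        dist = [(0.0, 1.0)]
        for el, n in self.counts.items():
            if el not in table:
                raise CompositionError(f"unknown element symbol: {el!r}")
            iso = [(m, a) for k, (m, a) in table[el].items() if k != 0 and a > 0]
            if not iso:
                iso = [(table[el][0][0], 1.0)]
            elem = _power_convolve(sorted(iso), n, prob_threshold * 1e-2, merge_tol)
            dist = _convolve(dist, elem, prob_threshold * 1e-2, merge_tol)
        mono = self.monoisotopic_mass(table)
        dist = [(m - mono, p) for m, p in dist if p >= prob_threshold]
        norm = sum(p for _, p in dist)
        if norm == 0:
            raise ValueError("prob_threshold pruned the entire pattern")
        return sorted(((m, p / norm) for m, p in dist), key=lambda t: t[0])

    # Formatting -------------------------------------------------------
    def formula(self) -> str:
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{el}{n if n != 1 else ''}" for el, n in ((e, self.counts[e]) for e in order))

    def __repr__(self) -> str:
        return f"ElementalComposition({self.counts!r})"


def _merge(dist: list[tuple[float, float]], tol: float) -> list[tuple[float, float]]:
    """Merge peaks within ``tol`` Da into abundance-weighted centroids."""
    dist = sorted(dist)
    out: list[list[float]] = []
    for m, p in dist:
        if out and m - out[-1][0] <= tol:
            m0, p0 = out[-1]
            tot = p0 + p
            out[-1] = [(m0 * p0 + m * p) / tot, tot]
        else:
            out.append([m, p])
    return [(m, p) for m, p in out]


def _convolve(a, b, prune, tol):
    prod = {}
    for ma, pa in a:
        for mb, pb in b:
            p = pa * pb
            if p < prune * 1e-3:
                continue
            key = round((ma + mb) / tol)
            if key in prod:
                m0, p0 = prod[key]
                prod[key] = ((m0 * p0 + (ma + mb) * p) / (p0 + p), p0 + p)
            else:
                prod[key] = (ma + mb, p)
    dist = _merge(list(prod.values()), tol)
    dist = [t for t in dist if t[1] >= prune]
    return dist


def _power_convolve(single, n, prune, tol):
    """Distribution of n i.i.d. atoms by binary exponentiation."""
    result = [(0.0, 1.0)]
    base = list(single)
    while n:
        if n & 1:
            result = _convolve(result, base, prune, tol)
        n >>= 1
        if n:
            base = _convolve(base, base, prune, tol)
    return result


# --- Peptides ----------------------------------------------------------

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: residue (in-chain) compositions for the 20 standard amino acids
RESIDUE_COMPOSITIONS: dict[str, ElementalComposition] = {
    aa: ElementalComposition(dict(_pmass.std_aa_comp[aa])) for aa in _STANDARD_RESIDUES
}

WATER = ElementalComposition({"H": 2, "O": 1})
HYDROGEN = ElementalComposition({"H": 1})
CO = ElementalComposition({"C": 1, "O": 1})
NH3 = ElementalComposition({"N": 1, "H": 3})


@dataclass(frozen=True)
class PeptideSequence:
    """A free-acid peptide: H– on the N terminus, –OH on the C terminus.

    Only the 20 standard residues are accepted; no modifications.
    """

    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("peptide must contain at least one residue")
        bad = [aa for aa in self.residues if aa not in _STANDARD_RESIDUES]
        if bad:
            raise ValueError(f"non-standard residue code(s): {bad}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def residue_composition(self, start: int, stop: int) -> ElementalComposition:
        """Sum of in-chain residue compositions for residues[start:stop] (0-based)."""
        total = ElementalComposition()
        for aa in self.residues[start:stop]:
            total = total + RESIDUE_COMPOSITIONS[aa]
        return total

    def composition(self) -> ElementalComposition:
        """Neutral free-acid composition: residues + H2O for the termini."""
        return self.residue_composition(0, len(self)) + WATER


# --- Functional spec surface -------------------------------------------

def parse_formula(text: str) -> ElementalComposition:
    """Parse an ``"C6H4NO2"``-style formula; an omitted count means 1."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise CompositionError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in DEFAULT_MASS_TABLE:
            raise CompositionError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text) or not counts:
        raise CompositionError(f"cannot parse formula {text!r} at position {pos}")
    return ElementalComposition(counts)


def combine(a: ElementalComposition, b: ElementalComposition, sign: int = 1) -> ElementalComposition:
    if sign == 1:
        return a + b
    if sign == -1:
        return a - b
    raise ValueError("sign must be +1 or -1")


def peptide_composition(seq: PeptideSequence | str) -> ElementalComposition:
    if isinstance(seq, str):
        seq = PeptideSequence(seq)
    return seq.composition()


def monoisotopic_mass(c: ElementalComposition) -> float:
    return c.monoisotopic_mass()


def average_mass(c: ElementalComposition) -> float:
    return c.average_mass()


def mz_of(c: ElementalComposition, charge: int, electron_correction: bool = True) -> float:
    return c.mz(charge, electron_correction=electron_correction)


def isotope_pattern(c: ElementalComposition, prob_threshold: float = 1e-4) -> list[tuple[float, float]]:
    return c.isotope_pattern(prob_threshold=prob_threshold)
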