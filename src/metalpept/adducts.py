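"""Metalated-ion model: backbone fragments, vanadium moieties, adduct ions.

The bookkeeping at the heart of this module is the formal vanadium
oxidation state of a metalated ion, derived purely from its label by
charge balance: the observed charge must equal the sum of proton charges
plus the metal oxidation state minus the charges of the oxido (O2-) and
monoanionic ligands it carries,

    z = n_protons + OS - 2*n_oxo - n_ligands.

Label convention (locked by the printed assignments it reproduces):
fragment symbols such as ``b6`` denote the canonical singly protonated
fragment ion, so they already carry one proton; whole-peptide symbols
(``M``, ``AT``, ``AT1``, ``AT2``) denote the neutral molecule.  ``- nH``
counts are relative to that.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .composition import (
    CO,
    NH3,
    WATER,
    HYDROGEN,
    CompositionError,
    ElementalComposition,
    PeptideSequence,
    parse_formula,
)

__all__ = [
    "Ligand",
    "LIGANDS",
    "MetalMoiety",
    "VO",
    "VO2",
    "VOL",
    "VOL2",
    "Fragment",
    "AdductIon",
    "LabelError",
    "enumerate_fragments",
    "oxidation_state",
    "enumerate_candidates",
    "parse_label",
    "format_label",
    "parse_moiety",
    "load_ligand_registry",
]

#: Oxidation states considered physiologically plausible for vanadium.
PLAUSIBLE_OS = frozenset({3, 4, 5})


@dataclass(frozen=True)
class Ligand:
    """A monoanionic chelator in its anion form (one H fewer than the acid)."""

    name: str
    composition: ElementalComposition | None  # None = generic placeholder "L"
    charge: int = -1

    def __post_init__(self):
        if self.charge != -1:
            raise ValueError("only monoanionic ligands are supported")


#: Built-in ligand registry: picolinate, maltolate and
#: 1,2-dimethyl-3-hydroxy-4(1H)-pyridinonate anions.
LIGANDS: dict[str, Ligand] = {
    "pic": Ligand("pic", parse_formula("C6H4NO2")),
    "ma": Ligand("ma", parse_formula("C6H5O3")),
    "dhp": Ligand("dhp", parse_formula("C7H8NO2")),
    "L": Ligand("L", None),
}


def load_ligand_registry(path) -> dict[str, Ligand]:
    """Extend the built-in registry from a YAML map name -> anion formula."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    registry = dict(LIGANDS)
    for name, formula in raw.items():
        registry[str(name)] = Ligand(str(name), parse_formula(str(formula)))
    return registry


@dataclass(frozen=True)
class MetalMoiety:
    """A vanadium unit: n_V metal centres, n_oxo oxido ligands, chelators."""

    n_v: int = 1
    n_oxo: int = 1
    ligands: tuple[Ligand, ...] = ()

    def __post_init__(self):
        if self.n_v < 1:
            raise ValueError("a metal moiety needs at least one vanadium")
        if self.n_oxo < 0:
            raise ValueError("n_oxo must be non-negative")

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    @property
    def composition(self) -> ElementalComposition:
        for lig in self.ligands:
            if lig.composition is None:
                raise CompositionError(
                    f"moiety {self.label} has a generic ligand with no formula; "
                    "supply a concrete ligand (pic/ma/dhp or custom)"
                )
        total = ElementalComposition({"V": self.n_v, "O": self.n_oxo})
        for lig in self.ligands:
            total = total + lig.composition
        return total

    @property
    def label(self) -> str:
        core = "VO" if self.n_oxo == 1 else f"VO{self.n_oxo}" if self.n_oxo else "V"
        if self.n_v > 1:
            core = f"{self.n_v}{core}"
        if not self.ligands:
            return core
        names = [lig.name for lig in self.ligands]
        if len(set(names)) != 1:
            return core + "".join(f"({n})" for n in names)
        n = names[0]
        lig = n if n == "L" else f"({n})"
        return core + lig + (str(len(names)) if len(names) > 1 else "")

    def __str__(self) -> str:
        return self.label


def VO() -> MetalMoiety:
    """Oxidovanadium unit [VO]."""
    return MetalMoiety(1, 1, ())


def VO2() -> MetalMoiety:
    """Dioxidovanadium unit [VO2]."""
    return MetalMoiety(1, 2, ())


def VOL(ligand: Ligand | str = "L") -> MetalMoiety:
    if isinstance(ligand, str):
        ligand = LIGANDS[ligand]
    return MetalMoiety(1, 1, (ligand,))


def VOL2(ligand: Ligand | str = "L") -> MetalMoiety:
    if isinstance(ligand, str):
        ligand = LIGANDS[ligand]
    return MetalMoiety(1, 1, (ligand, ligand))


_MOIETY_RE = re.compile(
    r"^(?P<count>\d*)V(?P<oxo>O\d?)?(?P<lig>L\d?|\([A-Za-z0-9]+\)\d?)?$"
)


def parse_moiety(text: str, registry: dict[str, Ligand] | None = None) -> MetalMoiety:
    """Parse moiety tokens like ``VO``, ``VO2``, ``VOL2``, ``VO(pic)2``, ``2VO``."""
    registry = registry or LIGANDS
    m = _MOIETY_RE.match(text.strip())
    if not m:
        raise LabelError(f"cannot parse metal moiety {text!r}")
    n_v = int(m.group("count") or 1)
    oxo = m.group("oxo") or ""
    n_oxo = 0 if not oxo else (1 if oxo == "O" else int(oxo[1:]))
    lig_tok = m.group("lig") or ""
    ligands: tuple[Ligand, ...] = ()
    if lig_tok:
        if lig_tok.startswith("L"):
            name, mult = "L", int(lig_tok[1:] or 1)
        else:
            body, _, tail = lig_tok.partition(")")
            name, mult = body[1:], int(tail or 1)
        if name not in registry:
            raise LabelError(f"unknown ligand {name!r} in moiety {text!r}")
        ligands = (registry[name],) * mult
    return MetalMoiety(n_v, n_oxo, ligands)


# --- Backbone fragments ------------------------------------------------

_SERIES = ("a", "b", "y", "z")


@dataclass(frozen=True)
class Fragment:
    """A backbone fragment of ``parent`` (series a/b/y/z, 1-based index).

    Composition convention: the canonical singly protonated fragment ion,
    i.e. b = N-terminal residues + H(+), a = b - CO,
    y = C-terminal residues + H2O + H(+), z = y - NH3 (deamination).
    """

    series: str
    index: int
    parent: PeptideSequence | None = None

    def __post_init__(self):
        if self.series not in _SERIES:
            raise ValueError(f"unknown fragment series {self.series!r}")
        if self.index < 1:
            raise ValueError("fragment index must be >= 1")
        if self.parent is not None and self.index >= len(self.parent):
            raise ValueError(
                f"{self.series}{self.index} is not a proper fragment of a "
                f"{len(self.parent)}-residue peptide"
            )

    @property
    def n_terminal(self) -> bool:
        return self.series in ("a", "b")

    def span(self) -> tuple[int, int]:
        """Residues covered, 1-based inclusive."""
        if self.parent is None:
            raise ValueError("fragment has no parent sequence")
        n = len(self.parent)
        return (1, self.index) if self.n_terminal else (n - self.index + 1, n)

    @property
    def composition(self) -> ElementalComposition:
        if self.parent is None:
            raise CompositionError(f"fragment {self.label} has no parent sequence")
        n = len(self.parent)
        if self.n_terminal:
            comp = self.parent.residue_composition(0, self.index) + HYDROGEN
            if self.series == "a":
                comp = comp - CO
        else:
            comp = self.parent.residue_composition(n - self.index, n) + WATER + HYDROGEN
            if self.series == "z":
                comp = comp - NH3
        return comp

    @property
    def label(self) -> str:
        prime = "″" if self.series == "y" else ""
        return f"{self.series}{self.index}{prime}"

    def __str__(self) -> str:
        return self.label


def enumerate_fragments(
    seq: PeptideSequence | str,
    series_set: Iterable[str] = ("a", "b", "y", "z"),
    index_range: Iterable[int] | None = None,
) -> list[Fragment]:
    """All a/b/y/z fragments of ``seq`` for the requested series/indices."""
    if isinstance(seq, str):
        seq = PeptideSequence(seq)
    series_set = tuple(series_set)
    for s in series_set:
        if s not in _SERIES:
            raise ValueError(f"unknown fragment series {s!r}")
    indices = tuple(index_range) if index_range is not None else tuple(range(1, len(seq)))
    out = []
    for s in series_set:
        for i in indices:
            if not 1 <= i < len(seq):
                raise ValueError(
                    f"fragment index {i} out of range for a {len(seq)}-residue peptide"
                )
            out.append(Fragment(s, i, seq))
    return out


# --- Adduct ions -------------------------------------------------------


class LabelError(ValueError):
    """Malformed bracket label."""


@dataclass(frozen=True)
class AdductIon:
    """A (possibly metalated) peptide or fragment ion.

    ``charge == 0`` denotes a neutral species (used for deconvoluted
    full-MS species); m/z is then undefined.  ``protons_added`` /
    ``protons_removed`` are relative to the label convention: fragments
    carry one canonical proton, whole peptides are neutral.
    """

    base: PeptideSequence | Fragment
    moieties: tuple[MetalMoiety, ...] = ()
    protons_added: int = 0
    protons_removed: int = 0
    charge: int = 1
    base_symbol: str | None = None  # how to print the whole-peptide base (M/AT/AT1/AT2)

    def __post_init__(self):
        if self.protons_added < 0 or self.protons_removed < 0:
            raise ValueError("proton adjustments must be non-negative")
        if self.charge < 0:
            raise ValueError("charge must be >= 0")

    # -- structural helpers -------------------------------------------
    @property
    def moiety(self) -> MetalMoiety | None:
        if not self.moieties:
            return None
        if len(self.moieties) == 1:
            return self.moieties[0]
        raise ValueError("ion carries more than one metal moiety")

    @property
    def is_fragment(self) -> bool:
        return isinstance(self.base, Fragment)

    @property
    def n_v(self) -> int:
        return sum(m.n_v for m in self.moieties)

    @property
    def net_protons(self) -> int:
        """Proton count including the canonical fragment proton."""
        canonical = 1 if self.is_fragment else 0
        return canonical + self.protons_added - self.protons_removed

    # -- derived chemistry ---------------------------------------------
    @property
    def oxidation_state(self) -> int:
        """Formal V oxidation state from charge balance (single-V ions only)."""
        if self.n_v == 0:
            raise ValueError("ion carries no vanadium")
        if self.n_v != 1:
            raise ValueError(
                "oxidation-state assignment is defined for exactly one V per ion"
            )
        n_oxo = sum(m.n_oxo for m in self.moieties)
        n_lig = sum(m.n_ligands for m in self.moieties)
        return self.charge - self.net_protons + 2 * n_oxo + n_lig

    @property
    def os_plausible(self) -> bool:
        return self.oxidation_state in PLAUSIBLE_OS

    @property
    def composition(self) -> ElementalComposition:
        if isinstance(self.base, Fragment):
            comp = self.base.composition
        else:
            comp = self.base.composition()
        for m in self.moieties:
            comp = comp + m.composition
        comp = comp + HYDROGEN * self.protons_added
        if self.protons_removed:
            comp = comp - HYDROGEN * self.protons_removed
        return comp

    def mz(self, electron_correction: bool = True) -> float:
        if self.charge < 1:
            raise ValueError("neutral species has no m/z")
        return self.composition.mz(self.charge, electron_correction=electron_correction)

    @property
    def neutral_mass(self) -> float:
        """Mass of the species with its charge-carrying protons removed."""
        from .composition import PROTON_MASS

        return self.composition.monoisotopic_mass() - self.charge * PROTON_MASS

    # -- labels ---------------------------------------------------------
    @property
    def label(self) -> str:
        return format_label(self)

    def __str__(self) -> str:
        return self.label


def oxidation_state(ion: AdductIon) -> int:
    """Formal vanadium oxidation state of ``ion`` (charge-balance bookkeeping)."""
    return ion.oxidation_state


# --- Label grammar -----------------------------------------------------

_LABEL_RE = re.compile(r"^\s*\[(?P<body>[^\[\]]+)\]\s*(?P<charge>\d*\+)?\s*$")
_FRAG_BASE_RE = re.compile(r"^(?P<series>[abyz])(?P<index>\d+)[″′\"']*$")
_H_TERM_RE = re.compile(r"^(?P<count>\d*)H$")
_PEPTIDE_SYMBOLS = {
    "M": None,
    "AT": None,
    "AT1": PeptideSequence("DRVYIHPFHL"),
    "AT2": PeptideSequence("DRVYIHPF"),
}


def parse_label(
    text: str,
    peptide: PeptideSequence | str | None = None,
    registry: dict[str, Ligand] | None = None,
) -> AdductIon:
    """Parse a bracket label like ``"[b6 + VO - 2H]+"`` into an :class:`AdductIon`.

    ``peptide`` supplies the parent sequence for fragment bases and for the
    generic whole-peptide symbols ``M``/``AT`` (the symbols ``AT1``/``AT2``
    resolve to the angiotensin sequences on their own).
    """
    if isinstance(peptide, str):
        peptide = PeptideSequence(peptide)
    m = _LABEL_RE.match(text)
    if not m:
        raise LabelError(f"malformed label {text!r}: expected '[...]' with optional charge")
    body = m.group("body")
    charge_tok = m.group("charge")
    charge = 0 if charge_tok is None else int(charge_tok[:-1] or 1)

    # split the body on top-level +/- separators (spaces required around them
    # in the printed labels; we accept any spacing)
    terms = re.split(r"\s+([+-])\s+", body.strip())
    base_tok = terms[0].strip()
    if not base_tok:
        raise LabelError(f"malformed label {text!r}: empty base at position 1")

    frag_m = _FRAG_BASE_RE.match(base_tok)
    base_symbol = None
    base: PeptideSequence | Fragment
    if frag_m:
        base = Fragment(frag_m.group("series"), int(frag_m.group("index")), peptide)
    elif base_tok in _PEPTIDE_SYMBOLS:
        seq = _PEPTIDE_SYMBOLS[base_tok] or peptide
        if seq is None:
            raise LabelError(
                f"label base {base_tok!r} needs an explicit peptide sequence"
            )
        base = seq
        base_symbol = base_tok
    else:
        raise LabelError(
            f"malformed label {text!r}: unknown base {base_tok!r} at position 1"
        )

    moieties: list[MetalMoiety] = []
    p = q = 0
    for sign_tok, term in zip(terms[1::2], terms[2::2]):
        term = term.strip()
        h_m = _H_TERM_RE.match(term)
        if h_m:
            n = int(h_m.group("count") or 1)
            if sign_tok == "+":
                p += n
            else:
                q += n
            continue
        if sign_tok == "-":
            raise LabelError(f"malformed label {text!r}: cannot subtract {term!r}")
        moieties.append(parse_moiety(term, registry))
    if len(terms) % 2 == 0:
        raise LabelError(f"malformed label {text!r}: dangling separator")

    return AdductIon(
        base=base,
        moieties=tuple(moieties),
        protons_added=p,
        protons_removed=q,
        charge=charge,
        base_symbol=base_symbol,
    )


def format_label(ion: AdductIon) -> str:
    """Canonical bracket label, inverse of :func:`parse_label`."""
    if isinstance(ion.base, Fragment):
        base = ion.base.label
    else:
        base = ion.base_symbol or "M"
    parts = [base]
    for m in ion.moieties:
        parts.append(f"+ {m.label}")
    if ion.protons_added:
        n = ion.protons_added
        parts.append(f"+ {n if n > 1 else ''}H")
    if ion.protons_removed:
        n = ion.protons_removed
        parts.append(f"- {n if n > 1 else ''}H")
    body = " ".join(parts)
    if ion.charge == 0:
        return f"[{body}]"
    z = ion.charge
    return f"[{body}]{z if z > 1 else ''}+"


# --- Candidate enumeration ---------------------------------------------

def neutral_adduct(
    peptide: PeptideSequence,
    moiety: MetalMoiety,
    os_per_v: int = 4,
    base_symbol: str | None = "AT",
) -> AdductIon:
    """The neutral adduct species formed by ``moiety`` displacing protons.

    Charge balance at the given oxidation state fixes the number of
    displaced protons: q = OS - 2 n_oxo - n_ligands (per V).  [VO2] units
    are vanadium(V); everything else defaults to vanadium(IV).
    """
    q = 0
    for m in (moiety,) if isinstance(moiety, MetalMoiety) else moiety:
        os_v = 5 if (m.n_oxo >= 2 and os_per_v == 4) else os_per_v
        q += os_v * m.n_v - 2 * m.n_oxo - m.n_ligands
    if q < 0:
        raise ValueError(f"moiety {moiety} cannot form a neutral adduct at OS {os_per_v}")
    return AdductIon(
        base=peptide,
        moieties=(moiety,) if isinstance(moiety, MetalMoiety) else tuple(moiety),
        protons_removed=q,
        charge=0,
        base_symbol=base_symbol,
    )


def enumerate_candidates(
    base: PeptideSequence | Fragment | Sequence,
    moieties: Iterable[MetalMoiety | None] = (None,),
    z_range: Iterable[int] = (1, 2),
    q_range: Iterable[int] = (0, 1, 2, 3),
    p_range: Iterable[int] = (0, 1, 2),
    os_allowed: frozenset[int] | set[int] = PLAUSIBLE_OS,
    include_implausible: bool = False,
) -> list[AdductIon]:
    """Cartesian enumeration of candidate adduct ions.

    Metal-free candidates are kept only when their proton count balances
    the charge exactly (z protons for a whole peptide, z-1 extra for a
    fragment which already carries one).  Single-V candidates are kept
    when their derived oxidation state lies in ``os_allowed`` (pass
    ``include_implausible=True`` to keep the rest, flagged via
    :attr:`AdductIon.os_plausible`).  Multi-V candidates are kept when the
    total metal charge corresponds to an average OS in [3, 5].
    Results are deduplicated by (composition, charge).
    """
    bases = [base] if isinstance(base, (PeptideSequence, Fragment)) else list(base)
    out: list[AdductIon] = []
    seen: set[tuple] = set()
    for b, mo, z, q, p in itertools.product(
        bases, moieties, z_range, q_range, p_range
    ):
        if z < 1:
            continue
        mo_tuple: tuple[MetalMoiety, ...]
        if mo is None:
            mo_tuple = ()
        elif isinstance(mo, MetalMoiety):
            mo_tuple = (mo,)
        else:
            mo_tuple = tuple(mo)
        ion = AdductIon(
            base=b,
            moieties=mo_tuple,
            protons_added=p,
            protons_removed=q,
            charge=z,
            base_symbol=None if isinstance(b, Fragment) else "M",
        )
        n_v = ion.n_v
        if n_v == 0:
            if ion.net_protons != z:
                continue
        elif n_v == 1:
            if not include_implausible and ion.oxidation_state not in os_allowed:
                continue
            if not 0 <= ion.oxidation_state <= 7:
                continue
        else:
            n_oxo = sum(m.n_oxo for m in mo_tuple)
            n_lig = sum(m.n_ligands for m in mo_tuple)
            total_os = z - ion.net_protons + 2 * n_oxo + n_lig
            if not 3 * n_v <= total_os <= 5 * n_v:
                continue
        try:
            comp = ion.composition
        except CompositionError:
            continue
        key = (comp, z)
        if key in seen:
            continue
        seen.add(key)
        out.append(ion)
    return out
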