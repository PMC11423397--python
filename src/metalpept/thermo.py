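"""Post-processing arithmetic for the DFT/EPR side of the study.

Nothing here runs quantum chemistry: these are the bookkeeping steps
applied to externally computed component energies and spin-Hamiltonian
parameters — assembling the aqueous Gibbs energy
G_aq = E_ele + G_therm + dG_solv (+ RT ln 24.46 standard-state term),
reaction free-energy differences, the percent deviation of calculated
51V hyperfine couplings from experiment, and a law-of-cosines check of
donor-metal-donor geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "HARTREE_TO_KCAL",
    "R_KCAL_PER_MOL_K",
    "standard_state_correction",
    "ThermoRecord",
    "ReactionSpec",
    "HyperfineRecord",
    "gibbs_aq",
    "reaction_delta_g",
    "percent_deviation",
    "donor_distance",
    "read_thermo_table",
    "write_gibbs_table",
]

HARTREE_TO_KCAL = 627.5095
R_KCAL_PER_MOL_K = 1.9872041e-3
#: Molar-volume ratio for the 1 atm gas -> 1 M solution standard-state change.
STANDARD_STATE_RATIO = 24.46

_UNIT_FACTORS = {"hartree": HARTREE_TO_KCAL, "kcal/mol": 1.0}


def standard_state_correction(temperature: float = 298.15) -> float:
    """RT ln(24.46) in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL_PER_MOL_K * temperature * math.log(STANDARD_STATE_RATIO)


@dataclass(frozen=True)
class ThermoRecord:
    """Component free energies of one species, unit-tagged.

    ``units`` is either a single tag applied to all three components or a
    map per field; the common convention of electronic/thermal terms in
    hartree with the solvation term in kcal/mol is expressed as
    ``units={"e_ele": "hartree", "g_therm": "hartree", "dg_solv": "kcal/mol"}``.
    """

    species: str
    e_ele: float
    g_therm: float
    dg_solv: float
    units: str | dict = "kcal/mol"
    temperature: float = 298.15

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        tags = (
            {f: self.units for f in ("e_ele", "g_therm", "dg_solv")}
            if isinstance(self.units, str)
            else dict(self.units)
        )
        for f in ("e_ele", "g_therm", "dg_solv"):
            tag = tags.get(f)
            if tag not in _UNIT_FACTORS:
                raise ValueError(
                    f"cannot resolve unit tag {tag!r} for field {f!r} "
                    f"(known: {sorted(_UNIT_FACTORS)})"
                )
        object.__setattr__(self, "units", tags)

    def component_kcal(self, name: str) -> float:
        return getattr(self, name) * _UNIT_FACTORS[self.units[name]]


def gibbs_aq(rec: ThermoRecord, standard_state: bool = False) -> float:
    """G_aq = E_ele + G_therm + dG_solv (+ RT ln 24.46), in kcal/mol."""
    total = sum(rec.component_kcal(f) for f in ("e_ele", "g_therm", "dg_solv"))
    if standard_state:
        total += standard_state_correction(rec.temperature)
    return total


@dataclass(frozen=True)
class ReactionSpec:
    """Stoichiometric reaction: lists of (species, positive integer count)."""

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]

    def __post_init__(self):
        for side in (self.reactants, self.products):
            for species, nu in side:
                if not isinstance(nu, int) or nu < 1:
                    raise ValueError(
                        f"stoichiometry for {species!r} must be a positive integer"
                    )
        object.__setattr__(self, "reactants", tuple(map(tuple, self.reactants)))
        object.__setattr__(self, "products", tuple(map(tuple, self.products)))

    @property
    def net_molecularity(self) -> int:
        return sum(n for _, n in self.products) - sum(n for _, n in self.reactants)

    def reversed(self) -> "ReactionSpec":
        return ReactionSpec(self.products, self.reactants)


def reaction_delta_g(
    rxn: ReactionSpec,
    g_values: dict[str, float],
    standard_state_per_molecularity: bool = False,
    temperature: float = 298.15,
) -> float:
    """dG_aq = sum(products) - sum(reactants), kcal/mol.

    With ``standard_state_per_molecularity`` on, the RT ln(24.46) term is
    applied once per unit of net molecularity change instead of being
    baked into each species' G_aq.
    """
    for species, _ in rxn.reactants + rxn.products:
        if species not in g_values:
            raise KeyError(f"no free energy supplied for species {species!r}")
    dg = sum(n * g_values[s] for s, n in rxn.products) - sum(
        n * g_values[s] for s, n in rxn.reactants
    )
    if standard_state_per_molecularity:
        dg += rxn.net_molecularity * standard_state_correction(temperature)
    return dg


@dataclass(frozen=True)
class HyperfineRecord:
    """Calculated and experimental axial 51V hyperfine couplings.

    Values in 1e-4 cm^-1; both are signed (A_z of vanadyl species is
    negative, though often quoted as |A_z|).
    """

    a_z_calc: float
    a_z_expt: float
    species: str = ""

    def __post_init__(self):
        if self.a_z_expt == 0:
            raise ValueError("experimental A_z must be nonzero")
        if self.a_z_calc == 0:
            raise ValueError("calculated A_z must be nonzero")


def percent_deviation(rec: HyperfineRecord, decimals: int | None = 1) -> float:
    """Percent deviation of |A_z calc| from |A_z exptl|.

    PD = 100 * (|A_z| - |A_z exptl|) / |A_z exptl| — the absolute-value
    form, which keeps the conventional sign (negative when the
    calculation underestimates the magnitude).
    """
    pd_val = 100.0 * (abs(rec.a_z_calc) - abs(rec.a_z_expt)) / abs(rec.a_z_expt)
    return round(pd_val, decimals) if decimals is not None else pd_val


def donor_distance(d1: float, d2: float, theta_deg: float) -> float:
    """Donor-donor distance from two bond lengths and the included angle.

    Law of cosines: sqrt(d1^2 + d2^2 - 2 d1 d2 cos theta).  Used to check
    that donor-metal geometries (e.g. the two His epsilon-nitrogens
    chelating one vanadium) are mutually consistent.
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError("bond lengths must be positive")
    if not 0 < theta_deg < 360:
        raise ValueError("angle must be in (0, 360) degrees")
    theta = math.radians(theta_deg)
    return math.sqrt(d1 * d1 + d2 * d2 - 2 * d1 * d2 * math.cos(theta))


# --- Tables ------------------------------------------------------------

def read_thermo_table(path) -> list[ThermoRecord]:
    """Load species records from TSV (species, e_ele, g_therm, dg_solv[, unit])
    or YAML (species -> {e_ele, g_therm, dg_solv, units})."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text()) or {}
        return [
            ThermoRecord(
                species=name,
                e_ele=float(rec["e_ele"]),
                g_therm=float(rec["g_therm"]),
                dg_solv=float(rec["dg_solv"]),
                units=rec.get("units", "kcal/mol"),
                temperature=float(rec.get("temperature", 298.15)),
            )
            for name, rec in raw.items()
        ]
    df = pd.read_csv(path, sep="\t")
    required = {"species", "e_ele", "g_therm", "dg_solv"}
    if not required.issubset(df.columns):
        raise ValueError(f"thermo table needs columns {sorted(required)}")
    return [
        ThermoRecord(
            species=row["species"],
            e_ele=float(row["e_ele"]),
            g_therm=float(row["g_therm"]),
            dg_solv=float(row["dg_solv"]),
            units=row.get("unit", "kcal/mol"),
        )
        for _, row in df.iterrows()
    ]


def write_gibbs_table(records: list[ThermoRecord], path, standard_state: bool = False) -> None:
    """Write species G_aq values (kcal/mol) as TSV."""
    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "g_aq_kcal_mol": [gibbs_aq(r, standard_state=standard_state) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
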