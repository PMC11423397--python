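"""Spectrum container, readers/writers (CSV, MGF, mzML) and result tables.

Intensities are arbitrary units throughout; only ratios are ever
interpreted, so normalization to the base peak (in %) is the canonical
reporting form.  CSV is the fixture dialect: two or three numeric
columns (m/z, intensity[, charge]) with ``#`` comments.  MGF and mzML go
through pyteomics; mzML is read-only.
"""

from __future__ import annotations

import base64
import json
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "AbundanceTable",
    "read_spectrum",
    "write_spectrum",
    "normalize_to_base_peak",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list with acquisition metadata.

    ``charges`` optionally carries a per-peak charge (0 = unknown), as
    provided e.g. by a third CSV column or by instrument centroiding.
    MS2 spectra must reference their precursor (bracket label) and may
    carry the HCD normalized collision energy (NCE).
    """

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    nce: float | None = None
    precursor: str | None = None
    isolation_window: float | None = None
    charges: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        charges = None if self.charges is None else np.asarray(self.charges, dtype=int)
        if charges is not None and charges.shape != mz.shape:
            raise ValueError("charges must match the peak list length")
        if mz.size and np.any(np.diff(mz) <= 0):
            if np.unique(mz).size < mz.size:
                warnings.warn("duplicate m/z values in peak list; sorting anyway")
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            if charges is not None:
                charges = charges[order]
        if self.ms_level == 2 and self.precursor is None:
            raise ValueError("an MS2 spectrum requires a precursor reference")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "charges", charges)

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_index(self) -> int:
        if not len(self):
            raise ValueError("empty spectrum has no base peak")
        return int(np.argmax(self.intensity))

    def replace(self, **kw) -> "Spectrum":
        return replace(self, **kw)


def normalize_to_base_peak(spectrum: Spectrum, base: int | None = None) -> Spectrum:
    """Rescale intensities so the chosen peak (default: the most intense)
    reads 100 %."""
    if not len(spectrum):
        raise ValueError("cannot normalize an empty spectrum")
    idx = spectrum.base_peak_index if base is None else int(base)
    ref = spectrum.intensity[idx]
    if ref <= 0:
        raise ValueError("base peak intensity is zero; cannot normalize")
    return spectrum.replace(intensity=spectrum.intensity * (100.0 / ref))


# --- Readers -----------------------------------------------------------

def _infer_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("mzml", "mgf", "csv"):
        return ext
    raise ValueError(f"cannot infer spectrum format from extension {path.suffix!r}")


def _read_csv(path: Path) -> list[Spectrum]:
    mz, inten, charges = [], [], []
    any_charge = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{ln}: expected 2-3 numeric columns")
            mz.append(float(parts[0]))
            inten.append(float(parts[1]))
            z = int(float(parts[2])) if len(parts) == 3 else 0
            any_charge = any_charge or z != 0
            charges.append(z)
    return [
        Spectrum(
            np.array(mz), np.array(inten),
            charges=np.array(charges) if any_charge else None,
            metadata={"source": str(path)},
        )
    ]


def _read_mgf(path: Path) -> list[Spectrum]:
    out = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            nce = params.get("collision_energy")
            pepmass = params.get("pepmass")
            title = params.get("title")
            meta = {"source": str(path)}
            if title:
                meta["title"] = title
            precursor = None
            if pepmass is not None:
                precursor = f"precursor m/z {pepmass[0]:.4f}"
                meta["pepmass"] = float(pepmass[0])
            if "charge" in params:
                meta["precursor_charge"] = int(params["charge"][0])
            ms_level = 2 if (pepmass is not None or nce is not None) else 1
            out.append(
                Spectrum(
                    entry["m/z array"],
                    entry["intensity array"],
                    ms_level=ms_level,
                    nce=float(nce) if nce is not None else None,
                    precursor=meta.get("title") or precursor if ms_level == 2 else None,
                    charges=entry.get("charge array"),
                    metadata=meta,
                )
            )
    return out


# mzML support is a minimal reader for centroided spectra (uncompressed or
# zlib 32/64-bit float arrays, the common instrument-export profile); the
# relevant cvParam accessions are matched by number.
_MZML_ACC = {
    "ms_level": "MS:1000511",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
    "f64": "MS:1000523",
    "f32": "MS:1000521",
    "zlib": "MS:1000574",
    "collision_energy": "MS:1000045",
    "selected_mz": "MS:1000744",
    "iso_lower": "MS:1000828",
    "iso_upper": "MS:1000829",
    "charge_state": "MS:1000041",
}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    payload = ""
    for el in bda.iter():
        name = _local(el.tag)
        if name == "cvParam":
            acc = el.get("accession")
            if acc == _MZML_ACC["f32"]:
                dtype = "<f4"
            elif acc == _MZML_ACC["zlib"]:
                compressed = True
        elif name == "binary":
            payload = el.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[Spectrum]:
    out = []
    for _, spec_el in ElementTree.iterparse(str(path)):
        if _local(spec_el.tag) != "spectrum":
            continue
        level = 1
        nce = None
        precursor = None
        iso_lo = iso_hi = None
        arrays: dict[str, np.ndarray] = {}
        for el in spec_el.iter():
            name = _local(el.tag)
            if name == "cvParam":
                acc, val = el.get("accession"), el.get("value")
                if acc == _MZML_ACC["ms_level"]:
                    level = int(val)
                elif acc == _MZML_ACC["collision_energy"]:
                    nce = float(val)
                elif acc == _MZML_ACC["selected_mz"]:
                    precursor = f"precursor m/z {float(val):.4f}"
                elif acc == _MZML_ACC["iso_lower"]:
                    iso_lo = float(val)
                elif acc == _MZML_ACC["iso_upper"]:
                    iso_hi = float(val)
            elif name == "binaryDataArray":
                accs = {c.get("accession") for c in el.iter() if _local(c.tag) == "cvParam"}
                data = _decode_binary_array(el)
                if _MZML_ACC["mz_array"] in accs:
                    arrays["mz"] = data
                elif _MZML_ACC["intensity_array"] in accs:
                    arrays["intensity"] = data
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: spectrum lacks m/z or intensity array")
        if level == 2 and precursor is None:
            precursor = "unknown precursor"
        out.append(
            Spectrum(
                arrays["mz"],
                arrays["intensity"],
                ms_level=level,
                nce=nce,
                precursor=precursor,
                isolation_window=(
                    iso_lo + iso_hi if iso_lo is not None and iso_hi is not None else None
                ),
                metadata={"source": str(path), "id": spec_el.get("id")},
            )
        )
        spec_el.clear()
    return out


def read_spectrum(path, fmt: str | None = None) -> list[Spectrum]:
    """Read one file into a list of :class:`Spectrum` (CSV holds a single one)."""
    path = Path(path)
    fmt = (fmt or _infer_format(path)).lower()
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "mgf":
        return _read_mgf(path)
    if fmt == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


# --- Writers -----------------------------------------------------------

def write_spectrum(spectra: Spectrum | list[Spectrum], path, fmt: str | None = None) -> None:
    """Write spectra to CSV (single spectrum) or MGF (any number)."""
    path = Path(path)
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    fmt = (fmt or _infer_format(path)).lower()
    if fmt == "csv":
        if len(spectra) != 1:
            raise ValueError("CSV holds exactly one spectrum")
        sp = spectra[0]
        with open(path, "w") as fh:
            fh.write("# m/z,intensity" + (",charge" if sp.charges is not None else "") + "\n")
            for i in range(len(sp)):
                row = f"{sp.mz[i]:.6f},{sp.intensity[i]:.6f}"
                if sp.charges is not None:
                    row += f",{int(sp.charges[i])}"
                fh.write(row + "\n")
        return
    if fmt == "mgf":
        entries = []
        for k, sp in enumerate(spectra):
            params = {"title": sp.metadata.get("title", sp.precursor or f"spectrum {k}")}
            if sp.ms_level == 2:
                params["pepmass"] = sp.metadata.get("pepmass", 0.0)
                if sp.nce is not None:
                    params["collision_energy"] = sp.nce
                if "precursor_charge" in sp.metadata:
                    params["charge"] = [sp.metadata["precursor_charge"]]
            entry = {
                "m/z array": sp.mz,
                "intensity array": sp.intensity,
                "params": params,
            }
            if sp.charges is not None:
                entry["charge array"] = sp.charges
            entries.append(entry)
        _mgf.write(entries, str(path), file_mode="w")
        return
    raise ValueError(f"unsupported output format {fmt!r} (CSV or MGF)")


# --- Abundance tables --------------------------------------------------

@dataclass
class AbundanceTable:
    """Species x system table of relative abundances in % of the base peak.

    The base-peak species row (the free peptide) reads 100 in every
    system; absent species read 0.00.
    """

    data: pd.DataFrame
    base_species: str | None = None

    def __post_init__(self):
        if (self.data.values < 0).any():
            raise ValueError("relative abundances must be non-negative")
        if self.base_species is not None and self.base_species in self.data.index:
            row = self.data.loc[self.base_species]
            if not np.allclose(row.values, 100.0):
                raise ValueError("base-peak species must read 100 in every system")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AbundanceTable)
            and self.base_species == other.base_species
            and self.data.shape == other.data.shape
            and list(self.data.index) == list(other.data.index)
            and list(self.data.columns) == list(other.data.columns)
            and np.allclose(self.data.values, other.data.values, atol=1e-6)
        )


def write_table(table, path, fmt: str | None = None) -> None:
    """Serialize an :class:`AbundanceTable` or a DataFrame to TSV or JSON."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    df = table.data if isinstance(table, AbundanceTable) else table
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index_label="species", float_format="%.6f")
        return
    if fmt == "json":
        payload = {
            "species": list(df.index),
            "systems": list(map(str, df.columns)),
            "values": df.values.tolist(),
        }
        if isinstance(table, AbundanceTable):
            payload["base_species"] = table.base_species
        path.write_text(json.dumps(payload, indent=1))
        return
    raise ValueError(f"unsupported table format {fmt!r} (TSV or JSON)")


def read_table(path, fmt: str | None = None) -> AbundanceTable:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col="species")
        return AbundanceTable(df)
    if fmt == "json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(
            payload["values"], index=payload["species"], columns=payload["systems"]
        )
        return AbundanceTable(df, base_species=payload.get("base_species"))
    raise ValueError(f"unsupported table format {fmt!r} (TSV or JSON)")
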