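"""MGF spectrum I/O, the shared spectrum data model, and the deglycopeptide
identification table reader.

Plain MGF files are read through :mod:`pyteomics.mgf`; writing uses a small
deterministic formatter so that repeated runs produce byte-identical files.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mgf as _mgf

from .chem import AA_MASSES, mz_from_neutral, neutral_mass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    """A single centroided peak; ``annotation`` is an optional ion label such
    as ``b3+1``, ``y5+2`` or ``Y0+1``."""

    mz: float
    intensity: float
    annotation: Optional[str] = None

    @property
    def is_annotated(self) -> bool:
        return self.annotation is not None


@dataclass
class MsmsSpectrum:
    """A peak list with precursor information; the unit of both query and
    library raw data. Peaks are kept sorted by m/z."""

    id: str
    precursor_mz: float
    charge: Optional[int]
    peaks: List[Peak]
    retention_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.mz, p.intensity))

    @property
    def precursor_neutral_mass(self) -> Optional[float]:
        if self.charge is None:
            return None
        return neutral_mass(self.precursor_mz, self.charge)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)

    def with_peaks(self, peaks: Sequence[Peak]) -> "MsmsSpectrum":
        return replace(self, peaks=list(peaks))

    def __len__(self) -> int:
        return len(self.peaks)


def read_mgf(path) -> List[MsmsSpectrum]:
    """Read an MGF file into a list of :class:`MsmsSpectrum`.

    Zero-intensity peaks are dropped at parse time (they cannot contribute to
    scoring or peak ranking). Spectra without a CHARGE line are kept with
    ``charge=None``; the search driver skips them and counts the exclusions.
    """
    path = Path(path)
    spectra: List[MsmsSpectrum] = []
    missing_charge = 0
    with _mgf.MGF(str(path)) as reader:
        for index, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"index={index}"))
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ValueError(f"{path}: block {index} ({title}): missing PEPMASS")
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            rt = params.get("rtinseconds")
            rt = float(rt) if rt is not None else None
            mz = np.asarray(entry["m/z array"], dtype=float)
            inten = np.asarray(entry["intensity array"], dtype=float)
            keep = inten > 0
            peaks = [Peak(float(m), float(i)) for m, i in zip(mz[keep], inten[keep])]
            if charge is None:
                missing_charge += 1
            spectra.append(
                MsmsSpectrum(
                    id=title,
                    precursor_mz=float(pepmass[0]),
                    charge=charge,
                    peaks=peaks,
                    retention_time=rt,
                )
            )
    if not spectra:
        warnings.warn(f"{path}: no spectra found")
    if missing_charge:
        logger.info("%s: %d spectra without CHARGE (kept, excluded from search)", path, missing_charge)
    return spectra


def write_mgf(spectra: Sequence[MsmsSpectrum], path) -> None:
    """Write spectra as MGF. Inverse of :func:`read_mgf` up to formatting."""
    with open(path, "w") as handle:
        for spectrum in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(f"TITLE={spectrum.id}\n")
            handle.write(f"PEPMASS={spectrum.precursor_mz:.6f}\n")
            if spectrum.charge is not None:
                handle.write(f"CHARGE={spectrum.charge}+\n")
            if spectrum.retention_time is not None:
                handle.write(f"RTINSECONDS={spectrum.retention_time:.3f}\n")
            for peak in spectrum.peaks:
                handle.write(f"{peak.mz:.6f} {peak.intensity:.6g}\n")
            handle.write("END IONS\n")


@dataclass(frozen=True)
class Modification:
    """A variable modification at a 1-based residue position."""

    position: int
    name: str
    delta: float


@dataclass
class PeptideIdentification:
    """One deglycopeptide identification row (the library input unit)."""

    spectrum_id: str
    sequence: str
    modifications: Tuple[Modification, ...]
    charge: int
    glycosites: Tuple[int, ...] = ()
    has_glycosite: bool = field(default=False)

    def __post_init__(self) -> None:
        self.has_glycosite = len(self.glycosites) > 0


#: Oracle-equivalent sequon pattern: Asn-Xaa-Ser/Thr(/Cys), Xaa != Pro.
SEQUON_PATTERN_STC = re.compile(r"(?=N[^P][STC])")
SEQUON_PATTERN_ST = re.compile(r"(?=N[^P][ST])")


def find_glycosites(sequence: str, include_cys: bool = True) -> Tuple[int, ...]:
    """Return the 1-based positions of Asn residues within an N-glycosylation
    sequon (N-X-S/T/C with X != P; Cys acceptance is switchable)."""
    pattern = SEQUON_PATTERN_STC if include_cys else SEQUON_PATTERN_ST
    return tuple(m.start() + 1 for m in pattern.finditer(sequence))


def _parse_modifications(text: str) -> Tuple[Modification, ...]:
    text = (text or "").strip()
    if text in ("", "-", "None", "null"):
        return ()
    mods = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(",")
        if len(parts) != 3:
            raise ValueError(f"malformed modification field: {chunk!r} (expected pos,name,delta)")
        mods.append(Modification(int(parts[0]), parts[1].strip(), float(parts[2])))
    return tuple(mods)


def format_modifications(mods: Sequence[Modification]) -> str:
    if not mods:
        return "-"
    return ";".join(f"{m.position},{m.name},{m.delta:.6f}" for m in mods)


REQUIRED_ID_COLUMNS = ("spectrum_id", "sequence", "modifications", "charge")


def read_identifications(path, include_cys: bool = True) -> List[PeptideIdentification]:
    """Read the tab-separated deglycopeptide identification table.

    Columns: ``spectrum_id``, ``sequence``, ``modifications`` (``-`` or
    ``pos,name,delta`` items joined by ``;``), ``charge``. Rows whose sequence
    contains no valid sequon are kept but flagged (``has_glycosite=False``)
    rather than silently dropped.
    """
    import pandas as pd

    table = pd.read_csv(path, sep="\t", dtype=str)
    for column in REQUIRED_ID_COLUMNS:
        if column not in table.columns:
            raise ValueError(f"{path}: missing required column {column!r}")
    rows: List[PeptideIdentification] = []
    no_site = 0
    for record in table.itertuples(index=False):
        sequence = str(record.sequence).strip()
        for i, residue in enumerate(sequence, start=1):
            if residue not in AA_MASSES:
                raise ValueError(f"{path}: unknown residue {residue!r} at position {i} in {sequence!r}")
        mods = _parse_modifications(str(record.modifications))
        for mod in mods:
            if mod.position < 0 or mod.position > len(sequence):
                raise ValueError(f"{path}: modification position {mod.position} outside {sequence!r}")
        sites = find_glycosites(sequence, include_cys=include_cys)
        if not sites:
            no_site += 1
        rows.append(
            PeptideIdentification(
                spectrum_id=str(record.spectrum_id),
                sequence=sequence,
                modifications=mods,
                charge=int(record.charge),
                glycosites=sites,
            )
        )
    if no_site:
        logger.info("%s: %d identification(s) without a valid sequon (flagged)", path, no_site)
    return rows


def write_identifications(rows: Sequence[PeptideIdentification], path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(REQUIRED_ID_COLUMNS) + "\n")
        for row in rows:
            handle.write(
                f"{row.spectrum_id}\t{row.sequence}\t{format_modifications(row.modifications)}\t{row.charge}\n"
            )


__all__ = [
    "Peak",
    "MsmsSpectrum",
    "Modification",
    "PeptideIdentification",
    "read_mgf",
    "write_mgf",
    "read_identifications",
    "write_identifications",
    "find_glycosites",
    "format_modifications",
    "mz_from_neutral",
]
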