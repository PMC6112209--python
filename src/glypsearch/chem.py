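"""Monoisotopic mass bookkeeping for peptides, modifications and glycans.

All residue masses are derived from atomic compositions via :mod:`pyteomics.mass`
rather than hard-coded decimals, so every constant can be audited against an
independent element-wise summation. The only non-standard residue is ``J``,
which denotes an Asn known to carry an N-glycan: it has exactly the mass of an
unmodified Asn residue, because the spectral library represents the bare
peptide and the glycan mass is added separately at search time.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from pyteomics import mass as _pmass

#: Mass of a proton (Da); used for every m/z <-> neutral-mass conversion.
PROTON: float = 1.00727646677
#: Monoisotopic mass of water (Da); the peptide terminus contribution.
WATER: float = _pmass.calculate_mass(formula="H2O")
#: Average C12/C13 isotope spacing (Da) used by the deisotoper.
ISOTOPE_SPACING: float = 1.00235

#: Atomic compositions of the monosaccharide *residues* (i.e. after loss of
#: water upon glycosidic bond formation).
MONOSACCHARIDE_FORMULAS: Dict[str, str] = {
    "Hex": "C6H10O5",
    "HexNAc": "C8H13NO5",
    "Fuc": "C6H10O4",
    "NeuAc": "C11H17NO8",
    "NeuGc": "C11H17NO9",
}

MONOSACCHARIDE_MASSES: Dict[str, float] = {
    name: _pmass.calculate_mass(formula=f) for name, f in MONOSACCHARIDE_FORMULAS.items()
}

#: Single-letter database notation (H5N4F1S2 ...) and common synonyms.
GLYCAN_ALIASES: Dict[str, str] = {
    "H": "Hex",
    "N": "HexNAc",
    "F": "Fuc",
    "S": "NeuAc",
    "G": "NeuGc",
    "dHex": "Fuc",
    "Hex": "Hex",
    "HexNAc": "HexNAc",
    "Fuc": "Fuc",
    "NeuAc": "NeuAc",
    "NeuGc": "NeuGc",
}

#: Canonical symbol order for rendering compositions as compact strings.
_SYMBOL_ORDER = ("Hex", "HexNAc", "Fuc", "NeuAc", "NeuGc")
_SYMBOL_LETTER = {"Hex": "H", "HexNAc": "N", "Fuc": "F", "NeuAc": "S", "NeuGc": "G"}

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residue masses for the 20 standard amino acids plus J (glycosylated Asn).
AA_MASSES: Dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in _STANDARD_AA}
AA_MASSES["J"] = AA_MASSES["N"]

#: Mass deltas of the modifications the library builder knows by name.
MODIFICATION_DELTAS: Dict[str, float] = {
    "Deamidation": _pmass.calculate_mass(formula="O") - _pmass.calculate_mass(formula="NH"),
    "HexNAc": MONOSACCHARIDE_MASSES["HexNAc"],
    "Oxidation": _pmass.calculate_mass(formula="O"),
    "Carbamidomethyl": _pmass.calculate_mass(formula="C2H3NO"),
}


def glycan_mass(counts: Mapping[str, int]) -> float:
    """Monoisotopic mass of a glycan composition (sum of residue masses).

    Parameters
    ----------
    counts
        Map from monosaccharide symbol (``Hex``, ``HexNAc``, ``Fuc``,
        ``NeuAc``, ``NeuGc`` or their single-letter aliases) to a
        non-negative integer count.
    """
    total = 0.0
    for symbol, count in counts.items():
        if symbol not in GLYCAN_ALIASES:
            raise ValueError(f"unknown monosaccharide symbol: {symbol!r}")
        if count < 0 or int(count) != count:
            raise ValueError(f"count for {symbol!r} must be a non-negative integer, got {count!r}")
        total += count * MONOSACCHARIDE_MASSES[GLYCAN_ALIASES[symbol]]
    return total


@dataclass(frozen=True)
class GlycanComposition:
    """A monosaccharide count vector with its monoisotopic mass."""

    counts: Tuple[Tuple[str, int], ...]
    mass: float = field(compare=False)

    def __init__(self, counts: Mapping[str, int]):
        canonical: Dict[str, int] = {}
        for symbol, count in counts.items():
            if symbol not in GLYCAN_ALIASES:
                raise ValueError(f"unknown monosaccharide symbol: {symbol!r}")
            name = GLYCAN_ALIASES[symbol]
            canonical[name] = canonical.get(name, 0) + int(count)
        items = tuple((s, canonical[s]) for s in _SYMBOL_ORDER if canonical.get(s, 0) > 0)
        object.__setattr__(self, "counts", items)
        object.__setattr__(self, "mass", glycan_mass(dict(items)))

    @classmethod
    def from_string(cls, text: str) -> "GlycanComposition":
        """Parse compact notation such as ``H5N4F1`` (letters per Fig-5 style:
        H=Hex, N=HexNAc, F=Fuc, S=NeuAc, G=NeuGc)."""
        text = text.strip()
        if not text:
            raise ValueError("empty glycan composition string")
        pos = 0
        counts: Dict[str, int] = {}
        for m in re.finditer(r"([HNFSG])(\d+)", text):
            if m.start() != pos:
                break
            letter, num = m.group(1), int(m.group(2))
            counts[letter] = counts.get(letter, 0) + num
            pos = m.end()
        if pos != len(text) or not counts:
            raise ValueError(f"malformed glycan composition: {text!r}")
        return cls(counts)

    def __str__(self) -> str:
        return "".join(f"{_SYMBOL_LETTER[s]}{c}" for s, c in self.counts)

    def total_count(self) -> int:
        return sum(c for _, c in self.counts)

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)


def load_glycan_db(path) -> List[GlycanComposition]:
    """Read a glycan composition database: one compact composition per line,
    blank lines and ``#`` comments allowed. Duplicates are collapsed with a
    warning; malformed lines raise with the offending line number."""
    path = Path(path)
    seen: Dict[str, GlycanComposition] = {}
    duplicates = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                comp = GlycanComposition.from_string(line)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            key = str(comp)
            if key in seen:
                duplicates += 1
            else:
                seen[key] = comp
    if duplicates:
        warnings.warn(f"{path}: collapsed {duplicates} duplicate glycan composition(s)")
    return list(seen.values())


def save_glycan_db(compositions: Iterable[GlycanComposition], path) -> None:
    with open(path, "w") as handle:
        handle.write("# glycan composition database (H=Hex N=HexNAc F=Fuc S=NeuAc G=NeuGc)\n")
        for comp in compositions:
            handle.write(f"{comp}\n")


def neutral_mass(mz: float, charge: int) -> float:
    """Neutral (uncharged, monoisotopic) mass from an observed m/z and charge."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return charge * (mz - PROTON)


def mz_from_neutral(mass_da: float, charge: int) -> float:
    """Inverse of :func:`neutral_mass`."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return mass_da / charge + PROTON


def peptide_neutral_mass(sequence: str, mods: Sequence[Tuple[int, float]] = ()) -> float:
    """Monoisotopic neutral mass of a (possibly J-encoded) peptide.

    ``mods`` is a sequence of ``(position, delta)`` pairs with 1-based residue
    positions; position 0 is accepted for N-terminal modifications.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER
    for i, residue in enumerate(sequence, start=1):
        try:
            total += AA_MASSES[residue]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r} at position {i}") from None
    for pos, delta in mods:
        if pos < 0 or pos > len(sequence):
            raise ValueError(f"modification position {pos} outside sequence of length {len(sequence)}")
        total += delta
    return total
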