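"""Query-spectrum classification and cleanup before matching.

A query spectrum is accepted as a glycopeptide spectrum only if it contains
the HexNAc internal-fragment diagnostic ion at 138.054953 Th. Accepted
spectra are then deisotoped, stripped of the 25 glycan oxonium ion species
(which carry no peptide information and would otherwise dominate the
dot-product), and thinned to at most 6 peaks per 100 Th window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from pyteomics import mass as _pmass

from .chem import ISOTOPE_SPACING, PROTON
from .params import SearchConfig, Tolerance
from .spectra import MsmsSpectrum, Peak

#: Diagnostic ion: HexNAc internal fragment (C7H7NO2 + proton).
DIAGNOSTIC_MZ: float = 138.054953

#: The default oxonium-ion table: 25 species derived from monosaccharide
#: residue compositions (singly protonated fragment formulas). Users may
#: supply their own TSV table instead.
_DEFAULT_OXONIUM_FORMULAS: Tuple[Tuple[str, str], ...] = (
    ("HexNAc_frag_126", "C6H7NO2"),
    ("HexNAc_frag_138", "C7H7NO2"),
    ("HexNAc_frag_144", "C6H9NO3"),
    ("HexNAc-2H2O", "C8H9NO3"),
    ("HexNAc-H2O", "C8H11NO4"),
    ("HexNAc", "C8H13NO5"),
    ("Hex-2H2O", "C6H6O3"),
    ("Hex-H2O", "C6H8O4"),
    ("Hex", "C6H10O5"),
    ("Fuc-H2O", "C6H8O3"),
    ("Fuc", "C6H10O4"),
    ("NeuAc-2H2O", "C11H13NO6"),
    ("NeuAc-H2O", "C11H15NO7"),
    ("NeuAc", "C11H17NO8"),
    ("NeuGc-H2O", "C11H15NO8"),
    ("NeuGc", "C11H17NO9"),
    ("Hex2", "C12H20O10"),
    ("HexHexNAc-H2O", "C14H21NO9"),
    ("HexHexNAc", "C14H23NO10"),
    ("HexNAc2", "C16H26N2O10"),
    ("NeuAcHex", "C17H27NO13"),
    ("Hex3", "C18H30O15"),
    ("FucHexHexNAc", "C20H33NO14"),
    ("Hex2HexNAc", "C20H33NO15"),
    ("NeuAcHexHexNAc", "C25H40N2O18"),
)


@dataclass(frozen=True)
class OxoniumTable:
    """Named oxonium ion m/z values to strip from query spectra."""

    entries: Tuple[Tuple[str, float], ...]
    diagnostic_mz: float = DIAGNOSTIC_MZ

    @classmethod
    def default(cls) -> "OxoniumTable":
        entries = tuple(
            (name, _pmass.calculate_mass(formula=formula) + PROTON)
            for name, formula in _DEFAULT_OXONIUM_FORMULAS
        )
        return cls(entries=entries)

    @classmethod
    def from_tsv(cls, path) -> "OxoniumTable":
        entries = []
        with open(path) as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.strip()
                if not line or line.startswith("#") or line.lower().startswith("name\t"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'name<TAB>mz'")
                entries.append((parts[0], float(parts[1])))
        return cls(entries=tuple(entries))

    def to_tsv(self, path) -> None:
        with open(Path(path), "w") as handle:
            handle.write("name\tmz\n")
            for name, mz in self.entries:
                handle.write(f"{name}\t{mz:.6f}\n")

    @property
    def mz_values(self) -> Tuple[float, ...]:
        return tuple(mz for _, mz in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def is_glycopeptide_spectrum(
    spectrum: MsmsSpectrum,
    fragment_tol: Tolerance,
    diagnostic_mz: float = DIAGNOSTIC_MZ,
) -> bool:
    """True iff some peak lies within the fragment tolerance of the 138.054953
    Th HexNAc diagnostic ion."""
    return any(fragment_tol.within(p.mz, diagnostic_mz) for p in spectrum.peaks)


def deisotope(
    spectrum: MsmsSpectrum,
    fragment_tol: Tolerance,
    max_charge: int = 2,
) -> MsmsSpectrum:
    """Remove isotopic peaks, keeping only the monoisotopic peak of each chain.

    Chains are built greedily left-to-right: starting from each unconsumed
    peak, successors are sought at spacings of 1.00235/z (z = 1..max_charge)
    within the fragment tolerance, requiring non-increasing intensity after
    the first isotope. For each starting peak the charge giving the longest
    chain wins; chain members other than the monoisotopic peak are removed.
    """
    peaks = spectrum.peaks
    removed = set()
    for i in range(len(peaks)):
        if i in removed:
            continue
        best_chain: List[int] = []
        for z in range(1, max_charge + 1):
            chain: List[int] = []
            current = i
            while True:
                expected = peaks[current].mz + ISOTOPE_SPACING / z
                tol_da = fragment_tol.da_at(expected)
                candidate = None
                candidate_err = None
                for j in range(current + 1, len(peaks)):
                    if j in removed:
                        continue
                    err = peaks[j].mz - expected
                    if err > tol_da:
                        break
                    if abs(err) <= tol_da:
                        if candidate is None or abs(err) < candidate_err:
                            candidate = j
                            candidate_err = abs(err)
                if candidate is None:
                    break
                # intensity must be non-increasing after the first isotope
                if chain and peaks[candidate].intensity > peaks[chain[-1]].intensity:
                    break
                chain.append(candidate)
                current = candidate
            if len(chain) > len(best_chain):
                best_chain = chain
        removed.update(best_chain)
    return spectrum.with_peaks([p for idx, p in enumerate(peaks) if idx not in removed])


def remove_oxonium(
    spectrum: MsmsSpectrum,
    table: OxoniumTable,
    fragment_tol: Tolerance,
) -> MsmsSpectrum:
    """Drop every peak within the fragment tolerance of any table entry."""
    kept = [
        p
        for p in spectrum.peaks
        if not any(fragment_tol.within(p.mz, ox_mz) for ox_mz in table.mz_values)
    ]
    return spectrum.with_peaks(kept)


def cap_peak_density(
    spectrum: MsmsSpectrum,
    max_per_window: int = 6,
    window: float = 100.0,
) -> MsmsSpectrum:
    """Within each fixed window [k*window, (k+1)*window) keep only the
    ``max_per_window`` most intense peaks; intensity ties are broken in favor
    of the lower-m/z peak."""
    bins = {}
    for peak in spectrum.peaks:
        bins.setdefault(int(peak.mz // window), []).append(peak)
    kept: List[Peak] = []
    for _, members in sorted(bins.items()):
        members.sort(key=lambda p: (-p.intensity, p.mz))
        kept.extend(members[:max_per_window])
    return spectrum.with_peaks(kept)


#: Reason codes attached to rejected query spectra.
REASON_NO_DIAGNOSTIC = "no_diagnostic_ion"
REASON_MISSING_CHARGE = "missing_charge"


@dataclass
class PreprocessResult:
    """Outcome of the query-preprocessing pipeline."""

    spectrum: Optional[MsmsSpectrum]
    reason: Optional[str] = None

    @property
    def passed(self) -> bool:
        return self.spectrum is not None


def preprocess_query(
    spectrum: MsmsSpectrum,
    config: SearchConfig,
    oxonium_table: Optional[OxoniumTable] = None,
    require_diagnostic: bool = True,
) -> PreprocessResult:
    """Run the full query pipeline: diagnostic-ion gate, deisotoping, oxonium
    removal, peak-density cap. Rejected spectra carry a reason code.

    The diagnostic ion is itself one of the stripped oxonium species, so the
    gate necessarily consumes its own evidence; pass ``require_diagnostic=False``
    to re-run the (idempotent) cleaning stages on an already-gated spectrum.
    """
    table = oxonium_table if oxonium_table is not None else OxoniumTable.default()
    if require_diagnostic and not is_glycopeptide_spectrum(
        spectrum, config.fragment_tol, config.diagnostic_mz
    ):
        return PreprocessResult(None, REASON_NO_DIAGNOSTIC)
    cleaned = deisotope(spectrum, config.fragment_tol, config.max_isotope_charge)
    cleaned = remove_oxonium(cleaned, table, config.fragment_tol)
    cleaned = cap_peak_density(cleaned, config.max_peaks_per_window, config.window_width)
    return PreprocessResult(cleaned)
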