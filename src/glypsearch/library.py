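"""Spectral-library construction from deglycopeptide identifications.

The builder groups identifications by (J-encoded peptide, remaining
modifications, charge), merges replicate spectra into a consensus, blends the
consensus with the theoretical b/y spectrum by a factor theta, repositions
annotated peaks at their theoretical m/z, injects the Y0..Y5 trimannosyl-core
ladder at 40% relative intensity, and finally emits one sequon-preserving
decoy per target so the search can estimate FDR = D/T.

The deglycosylation artifact mass (Deamidation for PNGase F input, a HexNAc
stub for HCD-pd-MS3 input) is stripped at every detected glycosite and those
Asn residues are rewritten as ``J``, so the library precursor represents the
bare peptide; the glycan mass is added back during candidate selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .chem import (
    MODIFICATION_DELTAS,
    MONOSACCHARIDE_MASSES,
    PROTON,
    WATER,
    AA_MASSES,
    mz_from_neutral,
    peptide_neutral_mass,
)
from .params import LibraryBuildConfig, Tolerance
from .spectra import (
    Modification,
    MsmsSpectrum,
    Peak,
    PeptideIdentification,
    format_modifications,
    _parse_modifications,
)

logger = logging.getLogger(__name__)

_HEXNAC = MONOSACCHARIDE_MASSES["HexNAc"]
_HEX = MONOSACCHARIDE_MASSES["Hex"]

#: Neutral-mass increments of the Y0..Y5 trimannosyl-core ladder relative to
#: the bare peptide: +0, +HexNAc, +2 HexNAc, then +1..3 Hex.
Y_CORE_DELTAS: Tuple[float, ...] = (
    0.0,
    _HEXNAC,
    2 * _HEXNAC,
    2 * _HEXNAC + _HEX,
    2 * _HEXNAC + 2 * _HEX,
    2 * _HEXNAC + 3 * _HEX,
)


def theoretical_by_ions(
    sequence: str,
    mods: Sequence[Modification] = (),
    precursor_charge: int = 2,
) -> List[Tuple[str, float]]:
    """All b/y fragment ions of a peptide at charges 1..min(2, precursor
    charge), as ``(annotation, mz)`` pairs with annotations like ``b3+1``.

    A peptide of length L yields 2(L-1) ion species per charge state."""
    if len(sequence) < 2:
        raise ValueError("peptide must have at least two residues")
    deltas = [0.0] * (len(sequence) + 1)
    for mod in mods:
        deltas[max(mod.position, 1)] += mod.delta
    residue = [AA_MASSES[aa] + deltas[i] for i, aa in enumerate(sequence, start=1)]
    max_charge = max(1, min(2, precursor_charge))
    ions: List[Tuple[str, float]] = []
    prefix = 0.0
    for i in range(1, len(sequence)):
        prefix += residue[i - 1]
        suffix = sum(residue[i:])
        for z in range(1, max_charge + 1):
            ions.append((f"b{i}+{z}", (prefix + z * PROTON) / z))
            ions.append((f"y{len(sequence) - i}+{z}", (suffix + WATER + z * PROTON) / z))
    ions.sort(key=lambda item: item[1])
    return ions


def y_core_ions(
    peptide_neutral_mass_da: float,
    charges: Sequence[int] = (1,),
) -> List[Tuple[str, float]]:
    """The six Y0..Y5 ions (bare peptide, +HexNAc, +2 HexNAc, +2 HexNAc and
    1..3 Hex) at the requested charge states, as ``(annotation, mz)`` pairs."""
    if peptide_neutral_mass_da <= 0:
        raise ValueError("peptide mass must be positive")
    ions = []
    for k, delta in enumerate(Y_CORE_DELTAS):
        for z in charges:
            ions.append((f"Y{k}+{z}", (peptide_neutral_mass_da + delta + z * PROTON) / z))
    return ions


@dataclass
class LibrarySpectrum:
    """An optimized consensus spectrum tied to a J-encoded peptide."""

    entry_id: str
    peptide: str
    modifications: Tuple[Modification, ...]
    charge: int
    precursor_neutral_mass: float
    glycosites: Tuple[int, ...]
    peaks: List[Peak]
    is_decoy: bool = False
    source_psm_count: int = 1

    @property
    def annotated_count(self) -> int:
        """m: the number of annotated (b/y and Y) peaks."""
        return sum(1 for p in self.peaks if p.is_annotated)

    @property
    def annotated_peaks(self) -> List[Peak]:
        return [p for p in self.peaks if p.is_annotated]

    def precursor_mz(self) -> float:
        return mz_from_neutral(self.precursor_neutral_mass, self.charge)


def derive_library_peptide(
    ident: PeptideIdentification,
    config: LibraryBuildConfig,
) -> Tuple[str, Tuple[Modification, ...], Tuple[int, ...]]:
    """Strip the deglycosylation artifact at every glycosite and rewrite those
    Asn residues as J. Modifications at non-glycosite positions (including
    genuine deamidations elsewhere) are kept."""
    sites = set(ident.glycosites)
    if not sites:
        raise ValueError(f"identification {ident.spectrum_id!r} has no glycosite")
    remove_name = config.modification_remove.lower()
    remove_delta = (
        config.modification_remove_delta
        if config.modification_remove_delta is not None
        else MODIFICATION_DELTAS.get(config.modification_remove)
    )
    remaining: List[Modification] = []
    for mod in ident.modifications:
        at_site = mod.position in sites
        matches = mod.name.lower().startswith(remove_name) or (
            remove_delta is not None and abs(mod.delta - remove_delta) < 0.01
        )
        if at_site and matches:
            continue
        remaining.append(mod)
    j_seq = "".join("J" if (i in sites) else aa for i, aa in enumerate(ident.sequence, start=1))
    return j_seq, tuple(remaining), tuple(sorted(sites))


def build_consensus(
    spectra: Sequence[MsmsSpectrum],
    fragment_tol: Tolerance,
) -> List[Peak]:
    """Merge replicate spectra of one identification into a consensus peak
    list: peaks agreeing within the fragment tolerance are combined into one
    peak with the averaged m/z and intensity (averaged over the replicates in
    which the peak occurs; peaks seen in only a subset are kept as-is)."""
    if not spectra:
        raise ValueError("build_consensus requires at least one spectrum")
    if len(spectra) == 1:
        return list(spectra[0].peaks)
    pooled = sorted((p for s in spectra for p in s.peaks), key=lambda p: p.mz)
    consensus: List[Peak] = []
    cluster: List[Peak] = []

    def flush() -> None:
        if cluster:
            n = len(cluster)
            consensus.append(
                Peak(sum(p.mz for p in cluster) / n, sum(p.intensity for p in cluster) / n)
            )

    for peak in pooled:
        if cluster:
            center = sum(p.mz for p in cluster) / len(cluster)
            if abs(peak.mz - center) <= fragment_tol.da_at(center):
                cluster.append(peak)
                continue
            flush()
            cluster = []
        cluster.append(peak)
    flush()
    return consensus


def _greedy_pairs(
    mz_a: Sequence[float],
    mz_b: Sequence[float],
    tol: Tolerance,
) -> List[Tuple[int, int]]:
    """One-to-one greedy pairing by ascending |delta m/z| within tolerance."""
    candidates = []
    j_start = 0
    for i, a in enumerate(mz_a):
        for j in range(len(mz_b)):
            d = mz_b[j] - a
            window = tol.da_at(max(a, mz_b[j]))
            if d > window:
                break
            if abs(d) <= window:
                candidates.append((abs(d), i, j))
    candidates.sort()
    used_a, used_b = set(), set()
    pairs = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def optimize_spectrum(
    consensus_peaks: Sequence[Peak],
    ident: PeptideIdentification,
    config: LibraryBuildConfig,
    entry_id: str = "T0",
    source_psm_count: int = 1,
) -> LibrarySpectrum:
    """Blend a consensus spectrum with the theoretical b/y spectrum.

    The consensus is normalized to base peak 1 and scaled by (1 - theta);
    theoretical peaks carry intensity theta. Common peaks are superimposed by
    intensity addition and repositioned at the theoretical m/z. The result is
    renormalized, and the Y0..Y5 ladder is appended at 40% relative intensity
    (at 1+ and, for precursor charge >= 2, also 2+).
    """
    j_seq, remaining, sites = derive_library_peptide(ident, config)
    pep_mass = peptide_neutral_mass(j_seq, [(m.position, m.delta) for m in remaining])
    theta = config.theta

    base = max((p.intensity for p in consensus_peaks), default=0.0)
    cons = [Peak(p.mz, p.intensity / base) for p in consensus_peaks] if base > 0 else []

    theo = theoretical_by_ions(j_seq, remaining, ident.charge)
    pairs = _greedy_pairs([p.mz for p in cons], [mz for _, mz in theo], config.fragment_tol)
    matched_cons = {i for i, _ in pairs}
    matched_theo = {j: i for i, j in pairs}

    merged: List[Peak] = []
    for j, (ann, mz) in enumerate(theo):
        if j in matched_theo:
            intensity = theta + (1 - theta) * cons[matched_theo[j]].intensity
        else:
            intensity = theta
        if intensity > 0:
            merged.append(Peak(mz, intensity, ann))
    for i, peak in enumerate(cons):
        if i not in matched_cons and (1 - theta) * peak.intensity > 0:
            merged.append(Peak(peak.mz, (1 - theta) * peak.intensity))

    top = max((p.intensity for p in merged), default=0.0)
    if top > 0:
        merged = [Peak(p.mz, p.intensity / top, p.annotation) for p in merged]

    y_charges = (1, 2) if ident.charge >= 2 else (1,)
    for ann, mz in y_core_ions(pep_mass, y_charges):
        merged.append(Peak(mz, config.y_ion_relative_intensity, ann))

    top = max((p.intensity for p in merged), default=0.0)
    if top > 0 and abs(top - 1.0) > 1e-12:
        merged = [Peak(p.mz, p.intensity / top, p.annotation) for p in merged]

    merged.sort(key=lambda p: (p.mz, p.intensity))
    return LibrarySpectrum(
        entry_id=entry_id,
        peptide=j_seq,
        modifications=remaining,
        charge=ident.charge,
        precursor_neutral_mass=pep_mass,
        glycosites=sites,
        peaks=merged,
        is_decoy=False,
        source_psm_count=source_psm_count,
    )


def sequon_preserving_reversal(
    sequence: str,
    glycosites: Sequence[int],
) -> Tuple[str, Dict[int, int]]:
    """Reverse a sequence while holding every sequon triplet (J, Xaa, S/T/C)
    at its absolute position. Returns the decoy sequence and the old->new
    1-based position map for the moved residues."""
    length = len(sequence)
    fixed = set()
    for site in glycosites:
        fixed.update(p for p in (site, site + 1, site + 2) if 1 <= p <= length)
    movable = [p for p in range(1, length + 1) if p not in fixed]
    position_map = {p: p for p in fixed}
    new_seq = list(sequence)
    for i, src in enumerate(movable):
        dest = movable[len(movable) - 1 - i]
        new_seq[dest - 1] = sequence[src - 1]
        position_map[src] = dest
    return "".join(new_seq), position_map


def make_decoy(target: LibrarySpectrum) -> LibrarySpectrum:
    """Generate the paired decoy spectrum: the sequence is reversed with the
    sequon held in place, modifications travel with their residues, annotated
    b/y peaks are recomputed at the decoy positions with their intensities
    preserved, and Y0..Y5 and unannotated peaks are left untouched. Precursor
    mass and charge are identical to the target's."""
    decoy_seq, position_map = sequon_preserving_reversal(target.peptide, target.glycosites)
    decoy_mods = tuple(
        Modification(position_map.get(m.position, m.position), m.name, m.delta)
        for m in target.modifications
    )
    decoy_mz = dict(theoretical_by_ions(decoy_seq, decoy_mods, target.charge))
    peaks = []
    for peak in target.peaks:
        ann = peak.annotation
        if ann is not None and ann[0] in "by":
            peaks.append(Peak(decoy_mz[ann], peak.intensity, ann))
        else:
            peaks.append(peak)
    peaks.sort(key=lambda p: (p.mz, p.intensity))
    return replace(
        target,
        entry_id=f"DECOY_{target.entry_id}",
        peptide=decoy_seq,
        modifications=decoy_mods,
        peaks=peaks,
        is_decoy=True,
    )


@dataclass
class SpectralLibrary:
    """A target+decoy spectral library with annotated-MGF persistence."""

    entries: List[LibrarySpectrum] = field(default_factory=list)

    @property
    def targets(self) -> List[LibrarySpectrum]:
        return [e for e in self.entries if not e.is_decoy]

    @property
    def decoys(self) -> List[LibrarySpectrum]:
        return [e for e in self.entries if e.is_decoy]

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, mgf_path, manifest_path=None) -> None:
        with open(mgf_path, "w") as handle:
            for entry in self.entries:
                handle.write("BEGIN IONS\n")
                handle.write(f"TITLE={entry.entry_id}\n")
                handle.write(f"PEPMASS={entry.precursor_mz():.6f}\n")
                handle.write(f"CHARGE={entry.charge}+\n")
                handle.write(f"PEPTIDE={entry.peptide}\n")
                handle.write(f"MODS={format_modifications(entry.modifications)}\n")
                handle.write(f"GLYCOSITES={';'.join(map(str, entry.glycosites))}\n")
                handle.write(f"DECOY={int(entry.is_decoy)}\n")
                handle.write(f"NPSM={entry.source_psm_count}\n")
                for peak in entry.peaks:
                    if peak.annotation:
                        handle.write(f"{peak.mz:.6f} {peak.intensity:.6g} # {peak.annotation}\n")
                    else:
                        handle.write(f"{peak.mz:.6f} {peak.intensity:.6g}\n")
                handle.write("END IONS\n")
        if manifest_path is not None:
            with open(manifest_path, "w") as handle:
                handle.write(
                    "entry_id\tpeptide\tmodifications\tcharge\tprecursor_neutral_mass"
                    "\tdecoy\tannotated_count\tn_peaks\tsource_psm_count\n"
                )
                for entry in self.entries:
                    handle.write(
                        f"{entry.entry_id}\t{entry.peptide}\t"
                        f"{format_modifications(entry.modifications)}\t{entry.charge}\t"
                        f"{entry.precursor_neutral_mass:.6f}\t{int(entry.is_decoy)}\t"
                        f"{entry.annotated_count}\t{len(entry.peaks)}\t{entry.source_psm_count}\n"
                    )

    @classmethod
    def load(cls, mgf_path) -> "SpectralLibrary":
        entries: List[LibrarySpectrum] = []
        meta: Dict[str, str] = {}
        peaks: List[Peak] = []
        with open(mgf_path) as handle:
            for raw in handle:
                line = raw.strip()
                if not line:
                    continue
                if line == "BEGIN IONS":
                    meta, peaks = {}, []
                elif line == "END IONS":
                    charge = int(meta["CHARGE"].rstrip("+"))
                    mz = float(meta["PEPMASS"])
                    sites = tuple(int(x) for x in meta["GLYCOSITES"].split(";") if x)
                    entries.append(
                        LibrarySpectrum(
                            entry_id=meta["TITLE"],
                            peptide=meta["PEPTIDE"],
                            modifications=_parse_modifications(meta.get("MODS", "-")),
                            charge=charge,
                            precursor_neutral_mass=charge * (mz - PROTON),
                            glycosites=sites,
                            peaks=sorted(peaks, key=lambda p: (p.mz, p.intensity)),
                            is_decoy=bool(int(meta.get("DECOY", "0"))),
                            source_psm_count=int(meta.get("NPSM", "1")),
                        )
                    )
                elif "=" in line and not line[0].isdigit():
                    key, value = line.split("=", 1)
                    meta[key] = value
                else:
                    annotation = None
                    if "#" in line:
                        line, annotation = (part.strip() for part in line.split("#", 1))
                    parts = line.split()
                    peaks.append(Peak(float(parts[0]), float(parts[1]), annotation))
        return cls(entries)


def build_library(
    identifications: Sequence[PeptideIdentification],
    spectra: Iterable[MsmsSpectrum],
    config: Optional[LibraryBuildConfig] = None,
) -> SpectralLibrary:
    """Build the optimized target library plus one paired decoy per target.

    Identifications are grouped by (J-encoded peptide, remaining
    modifications, charge); each group yields one consensus + optimized target
    spectrum. Identifications without a glycosite and rows whose spectrum_id
    cannot be resolved are skipped with a warning count."""
    config = config or LibraryBuildConfig()
    by_id = {s.id: s for s in spectra}
    groups: Dict[Tuple[str, Tuple[Modification, ...], int], List[Tuple[PeptideIdentification, MsmsSpectrum]]] = {}
    skipped_no_site = 0
    skipped_unresolved = 0
    for ident in identifications:
        if not ident.has_glycosite:
            skipped_no_site += 1
            continue
        spectrum = by_id.get(ident.spectrum_id)
        if spectrum is None:
            skipped_unresolved += 1
            continue
        j_seq, remaining, _ = derive_library_peptide(ident, config)
        groups.setdefault((j_seq, remaining, ident.charge), []).append((ident, spectrum))
    if skipped_no_site:
        logger.warning("skipped %d identification(s) without a glycosite", skipped_no_site)
    if skipped_unresolved:
        logger.warning("skipped %d identification(s) with unresolvable spectrum_id", skipped_unresolved)

    entries: List[LibrarySpectrum] = []
    degenerate_decoys = 0
    for index, key in enumerate(sorted(groups, key=lambda k: (k[0], k[2], tuple(str(m) for m in k[1])))):
        members = groups[key]
        consensus = build_consensus([s for _, s in members], config.fragment_tol)
        target = optimize_spectrum(
            consensus, members[0][0], config,
            entry_id=f"T{index:05d}", source_psm_count=len(members),
        )
        decoy = make_decoy(target)
        if decoy.peptide == target.peptide:
            degenerate_decoys += 1
        entries.append(target)
        entries.append(decoy)
    if degenerate_decoys:
        logger.info("%d decoy(s) identical to their target (palindromic residues)", degenerate_decoys)
    return SpectralLibrary(entries)
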