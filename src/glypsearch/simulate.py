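"""Deterministic synthetic fixtures with known ground truth.

The generator emulates the anatomy of HCD glycopeptide data well enough to
exercise every stage of the pipeline without any download: deglycopeptide
replicate spectra (b/y ladders with a deamidation artifact at the glycosite,
log-normal intensities, ppm mass jitter, uniform noise) for library
construction, and intact-glycopeptide query spectra (glycosite-free b/y ions,
a Y0..Y5 core ladder, oxonium ions including the 138.054953 diagnostic, and
noise) whose precursor carries the full glycan mass. Pure-noise queries mimic
the same precursor mass range without any fragment signal.

Everything is drawn from a single seeded generator, so a fixed seed
reproduces the fixtures byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import GlycanComposition, MODIFICATION_DELTAS, peptide_neutral_mass
from .library import theoretical_by_ions, y_core_ions
from .preprocess import DIAGNOSTIC_MZ, OxoniumTable
from .spectra import (
    Modification,
    MsmsSpectrum,
    Peak,
    PeptideIdentification,
    find_glycosites,
    mz_from_neutral,
)

#: Residues used for peptide bodies: no K/R (kept tryptic-terminal), no N or P
#: (so the only sequon is the planted one), no J.
_BODY_ALPHABET = "ACDEFGHILMQSTVWY"
_DEAMIDATION = MODIFICATION_DELTAS["Deamidation"]


@dataclass
class FixtureConfig:
    """All the knobs of the synthetic benchmark.

    The defaults define the desk-scale study conditions: 200 glycopeptides
    crossed with an 85-composition glycan database, 500 true glycopeptide
    queries plus 500 pure-noise queries.
    """

    n_peptides: int = 200
    peptide_length: Tuple[int, int] = (8, 16)
    n_glycans: int = 85
    n_true_queries: int = 500
    noise_fraction: float = 0.5
    replicate_range: Tuple[int, int] = (2, 3)
    by_detect_prob: float = 0.7
    y_detect_prob: float = 0.6
    oxonium_intensity: Tuple[float, float] = (0.5, 1.0)
    noise_peaks_per_100: float = 2.0
    intensity_sigma: float = 0.4
    mass_jitter_ppm: float = 3.0
    mz_min: float = 100.0
    mz_max: float = 2000.0
    seed: int = 0

    @property
    def n_noise_queries(self) -> int:
        return int(round(self.n_true_queries * self.noise_fraction / (1.0 - self.noise_fraction)))


@dataclass
class SimulatedPeptide:
    sequence: str
    glycosite: int
    charge: int


@dataclass
class FixtureBundle:
    """Everything a full benchmark run needs, plus the ground truth."""

    peptides: List[SimulatedPeptide]
    glycans: List[GlycanComposition]
    identifications: List[PeptideIdentification]
    library_spectra: List[MsmsSpectrum]
    queries: List[MsmsSpectrum]
    truth: pd.DataFrame


def default_glycan_db(n: int = 85) -> List[GlycanComposition]:
    """A representative N-glycan composition database: HexNAc 2-6, Hex 3-8,
    optional core fucose, up to two NeuAc on complex compositions; ``n``
    compositions evenly spaced by mass across the enumeration."""
    pool = []
    for hexnac in range(2, 7):
        for hexose in range(3, 9):
            for fuc in range(0, 2):
                for neuac in range(0, min(2, hexnac - 2) + 1):
                    pool.append(
                        GlycanComposition(
                            {"Hex": hexose, "HexNAc": hexnac, "Fuc": fuc, "NeuAc": neuac}
                        )
                    )
    pool.sort(key=lambda g: (g.mass, str(g)))
    if n >= len(pool):
        return pool
    indices = np.linspace(0, len(pool) - 1, n).round().astype(int)
    return [pool[i] for i in sorted(set(indices.tolist()))]


def generate_peptides(config: FixtureConfig, rng: np.random.Generator) -> List[SimulatedPeptide]:
    """Random tryptic-like peptides (C-terminal K/R, no internal K/R), each
    containing exactly one N-X-S/T sequon."""
    peptides: List[SimulatedPeptide] = []
    seen = set()
    while len(peptides) < config.n_peptides:
        length = int(rng.integers(config.peptide_length[0], config.peptide_length[1] + 1))
        body = [str(x) for x in rng.choice(list(_BODY_ALPHABET), size=length - 1)]
        site = int(rng.integers(1, length - 2))  # 1-based; sequon within body
        body[site - 1] = "N"
        body[site] = str(rng.choice([c for c in _BODY_ALPHABET if c != "P"]))
        body[site + 1] = str(rng.choice(["S", "T"]))
        sequence = "".join(body) + str(rng.choice(["K", "R"]))
        if sequence in seen or find_glycosites(sequence) != (site,):
            continue
        seen.add(sequence)
        charge = int(rng.choice([2, 3]))
        peptides.append(SimulatedPeptide(sequence, site, charge))
    return peptides


def _jitter(mz: float, ppm_sd: float, rng: np.random.Generator) -> float:
    return mz * (1.0 + rng.normal(0.0, ppm_sd) * 1e-6)


def _noise_peaks(
    config: FixtureConfig, rng: np.random.Generator, scale: float = 0.05
) -> List[Peak]:
    span = config.mz_max - config.mz_min
    count = rng.poisson(config.noise_peaks_per_100 * span / 100.0)
    peaks = []
    for _ in range(count):
        mz = float(rng.uniform(config.mz_min, config.mz_max))
        peaks.append(Peak(mz, scale * float(rng.lognormal(0.0, config.intensity_sigma))))
    return peaks


def generate_library_spectra(
    peptides: Sequence[SimulatedPeptide],
    config: FixtureConfig,
    rng: np.random.Generator,
) -> Tuple[List[PeptideIdentification], List[MsmsSpectrum]]:
    """Replicate deglycopeptide spectra plus their identification rows.

    Each spectrum is the b/y ladder of the deamidated peptide, sampled at the
    detection probability with log-normal intensities and ppm jitter, plus
    uniform noise."""
    identifications: List[PeptideIdentification] = []
    spectra: List[MsmsSpectrum] = []
    for i, pep in enumerate(peptides):
        mods = (Modification(pep.glycosite, "Deamidation", _DEAMIDATION),)
        mass = peptide_neutral_mass(pep.sequence, [(m.position, m.delta) for m in mods])
        ions = theoretical_by_ions(pep.sequence, mods, pep.charge)
        n_rep = int(rng.integers(config.replicate_range[0], config.replicate_range[1] + 1))
        for rep in range(n_rep):
            peaks: List[Peak] = []
            for _, mz in ions:
                if rng.random() < config.by_detect_prob and config.mz_min <= mz <= config.mz_max:
                    peaks.append(
                        Peak(
                            _jitter(mz, config.mass_jitter_ppm, rng),
                            0.3 * float(rng.lognormal(0.0, config.intensity_sigma)),
                        )
                    )
            peaks.extend(_noise_peaks(config, rng))
            spectrum_id = f"lib{i:04d}_r{rep}"
            spectra.append(
                MsmsSpectrum(
                    id=spectrum_id,
                    precursor_mz=_jitter(
                        mz_from_neutral(mass, pep.charge), config.mass_jitter_ppm, rng
                    ),
                    charge=pep.charge,
                    peaks=peaks,
                )
            )
            identifications.append(
                PeptideIdentification(
                    spectrum_id=spectrum_id,
                    sequence=pep.sequence,
                    modifications=mods,
                    charge=pep.charge,
                    glycosites=(pep.glycosite,),
                )
            )
    return identifications, spectra


def _oxonium_peaks(config: FixtureConfig, rng: np.random.Generator) -> List[Peak]:
    table = OxoniumTable.default()
    low, high = config.oxonium_intensity
    peaks = [Peak(_jitter(DIAGNOSTIC_MZ, config.mass_jitter_ppm, rng), float(rng.uniform(low, high)))]
    others = [mz for _, mz in table.entries if abs(mz - DIAGNOSTIC_MZ) > 0.01]
    count = int(rng.integers(3, 7))
    chosen = rng.choice(len(others), size=count, replace=False)
    for idx in sorted(chosen.tolist()):
        peaks.append(
            Peak(_jitter(others[idx], config.mass_jitter_ppm, rng), float(rng.uniform(low, high)))
        )
    return peaks


def generate_glyco_queries(
    peptides: Sequence[SimulatedPeptide],
    glycans: Sequence[GlycanComposition],
    config: FixtureConfig,
    rng: np.random.Generator,
) -> Tuple[List[MsmsSpectrum], pd.DataFrame]:
    """Intact-glycopeptide query spectra plus the ground-truth table.

    True queries carry glycosite-free b/y ions of the bare peptide, a sampled
    subset of the Y0..Y5 ladder, oxonium ions (always including the
    138.054953 diagnostic) and noise; the precursor is peptide + glycan mass
    with ppm jitter. Noise queries share the precursor mass distribution but
    contain no fragment signal."""
    queries: List[MsmsSpectrum] = []
    truth_rows = []
    for q in range(config.n_true_queries):
        pep = peptides[int(rng.integers(len(peptides)))]
        glycan = glycans[int(rng.integers(len(glycans)))]
        site = pep.glycosite
        length = len(pep.sequence)
        j_seq = pep.sequence[: site - 1] + "J" + pep.sequence[site:]
        bare_mass = peptide_neutral_mass(j_seq)
        charge = int(rng.choice([2, 3]))
        peaks: List[Peak] = []
        for ann, mz in theoretical_by_ions(pep.sequence, (), charge):
            series, rest = ann[0], ann[1:].split("+")
            idx = int(rest[0])
            contains_site = idx >= site if series == "b" else idx >= length - site + 1
            if contains_site:
                continue
            if rng.random() < config.by_detect_prob and config.mz_min <= mz <= config.mz_max:
                peaks.append(
                    Peak(
                        _jitter(mz, config.mass_jitter_ppm, rng),
                        0.3 * float(rng.lognormal(0.0, config.intensity_sigma)),
                    )
                )
        for ann, mz in y_core_ions(bare_mass, (1, 2)):
            if rng.random() < config.y_detect_prob and config.mz_min <= mz <= config.mz_max:
                peaks.append(
                    Peak(
                        _jitter(mz, config.mass_jitter_ppm, rng),
                        0.35 * float(rng.lognormal(0.0, config.intensity_sigma)),
                    )
                )
        peaks.extend(_oxonium_peaks(config, rng))
        peaks.extend(_noise_peaks(config, rng))
        neutral = bare_mass + glycan.mass
        precursor_mz = _jitter(mz_from_neutral(neutral, charge), config.mass_jitter_ppm, rng)
        query_id = f"query{q:04d}"
        queries.append(MsmsSpectrum(query_id, precursor_mz, charge, peaks))
        truth_rows.append(
            {
                "query_id": query_id,
                "peptide": j_seq,
                "glycan": str(glycan),
                "charge": charge,
                "is_noise": False,
            }
        )
    for q in range(config.n_noise_queries):
        pep = peptides[int(rng.integers(len(peptides)))]
        glycan = glycans[int(rng.integers(len(glycans)))]
        site = pep.glycosite
        j_seq = pep.sequence[: site - 1] + "J" + pep.sequence[site:]
        charge = int(rng.choice([2, 3]))
        neutral = peptide_neutral_mass(j_seq) + glycan.mass
        peaks = _oxonium_peaks(config, rng)
        peaks.extend(_noise_peaks(config, rng, scale=0.3))
        precursor_mz = _jitter(mz_from_neutral(neutral, charge), config.mass_jitter_ppm, rng)
        query_id = f"noise{q:04d}"
        queries.append(MsmsSpectrum(query_id, precursor_mz, charge, peaks))
        truth_rows.append(
            {
                "query_id": query_id,
                "peptide": "",
                "glycan": "",
                "charge": charge,
                "is_noise": True,
            }
        )
    return queries, pd.DataFrame(truth_rows)


def evaluate_identifications(accepted, truth: pd.DataFrame) -> Dict[str, float]:
    """Score accepted GPSMs against the ground truth: an accepted target is
    correct iff its query is a true query and both the J-encoded peptide and
    the glycan composition string match the planted pair."""
    indexed = truth.set_index("query_id")
    n_true = int((~truth["is_noise"]).sum())
    n_correct = 0
    for gpsm in accepted:
        row = indexed.loc[gpsm.query_id]
        if (
            not row["is_noise"]
            and gpsm.library.peptide == row["peptide"]
            and str(gpsm.glycan) == row["glycan"]
        ):
            n_correct += 1
    n_accepted = len(accepted)
    return {
        "n_true_queries": n_true,
        "n_accepted": n_accepted,
        "n_correct": n_correct,
        "recovery": n_correct / n_true if n_true else float("nan"),
        "false_rate": (n_accepted - n_correct) / n_accepted if n_accepted else 0.0,
    }


def generate_benchmark(config: Optional[FixtureConfig] = None) -> FixtureBundle:
    """Generate the full benchmark bundle from one seeded generator."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    peptides = generate_peptides(config, rng)
    glycans = default_glycan_db(config.n_glycans)
    identifications, library_spectra = generate_library_spectra(peptides, config, rng)
    queries, truth = generate_glyco_queries(peptides, glycans, config, rng)
    return FixtureBundle(
        peptides=peptides,
        glycans=glycans,
        identifications=identifications,
        library_spectra=library_spectra,
        queries=queries,
        truth=truth,
    )
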