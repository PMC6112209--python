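"""Open spectral-library search with the dot-product x binomial score.

For a query spectrum of neutral mass M_q, every (library spectrum, glycan)
pair with |M_lib + M_glycan - M_q| within the precursor tolerance is a
candidate; target and decoy entries are equally eligible. Each candidate is
scored as the product of two subscores:

* DPS, a normalized spectral dot product over all matched peak pairs, and
* PS, minus log10 of the binomial upper-tail probability that k or more of
  the top-n query peaks (relative intensity >= 0.05, at most 12) match the
  candidate's m annotated peaks by chance, with single-peak match probability
  p = 2 * pro_tol / mz_range and P = 1 - (1-p)^m.

The candidate with the highest score is the reported GPSM; a best match with
score zero is suppressed. Score ties are broken by the smaller absolute
precursor ppm error; deeper ties fall through to a stable content hash so
that the target/decoy composition of the ranked diagnostics (used for FDR
validation) carries no systematic flag bias.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import GlycanComposition
from .library import LibrarySpectrum, SpectralLibrary, _greedy_pairs
from .params import SearchConfig, Tolerance
from .preprocess import OxoniumTable, preprocess_query, REASON_MISSING_CHARGE
from .spectra import MsmsSpectrum, Peak, format_modifications

logger = logging.getLogger(__name__)


@dataclass
class ScoreDetail:
    """The ingredients of one candidate score."""

    n: int
    k: int
    m: int
    p: float
    P: float
    dps: float
    ps: float

    @property
    def score(self) -> float:
        return self.dps * self.ps


@dataclass
class Gpsm:
    """A scored glycopeptide-spectrum match."""

    query_id: str
    library: LibrarySpectrum
    glycan: GlycanComposition
    charge: Optional[int]
    precursor_error_ppm: float
    detail: ScoreDetail
    rank: int = 0

    @property
    def is_decoy(self) -> bool:
        return self.library.is_decoy

    @property
    def score(self) -> float:
        return self.detail.score


def match_peaks(
    query_peaks: Sequence[Peak],
    library_peaks: Sequence[Peak],
    fragment_tol: Tolerance,
) -> List[Tuple[int, int]]:
    """One-to-one peak pairing, greedy by ascending |delta m/z| within the
    fragment tolerance. Returns (query index, library index) pairs."""
    return _greedy_pairs(
        [p.mz for p in query_peaks], [p.mz for p in library_peaks], fragment_tol
    )


def dps(
    query: MsmsSpectrum,
    candidate: LibrarySpectrum,
    fragment_tol: Tolerance,
) -> float:
    """Normalized spectral dot product: sum of I_Q * I_L over matched pairs
    divided by the product of the intensity norms of the two full spectra.
    Lies in [0, 1] by Cauchy-Schwarz; empty spectra score 0 by convention."""
    if not query.peaks or not candidate.peaks:
        return 0.0
    pairs = match_peaks(query.peaks, candidate.peaks, fragment_tol)
    if not pairs:
        return 0.0
    numerator = sum(query.peaks[i].intensity * candidate.peaks[j].intensity for i, j in pairs)
    qnorm = math.sqrt(sum(p.intensity**2 for p in query.peaks))
    lnorm = math.sqrt(sum(p.intensity**2 for p in candidate.peaks))
    return numerator / (qnorm * lnorm)


def random_match_prob(fragment_tol_da: float, mz_range: float) -> float:
    """p = 2 * pro_tol / mz_range: the probability that one query peak falls
    within the product tolerance of one annotated peak by chance. Depends only
    on the tolerance and scan range, not on the candidate set."""
    if not 0 < 2 * fragment_tol_da < mz_range:
        raise ValueError("require 0 < 2*tolerance < mz_range")
    return 2.0 * fragment_tol_da / mz_range


def elevate(p: float, m: int) -> float:
    """P = 1 - (1-p)^m: chance that a query peak matches any of the m
    annotated peaks of a candidate."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - p) ** m


def binomial_tail(n: int, k: int, P: float) -> float:
    """Exact upper tail: sum_{j=k}^{n} C(n,j) P^j (1-P)^(n-j)."""
    return sum(math.comb(n, j) * P**j * (1.0 - P) ** (n - j) for j in range(k, n + 1))


def top_n_peaks(query: MsmsSpectrum, config: SearchConfig) -> List[Peak]:
    """The query peaks entering the probability score: relative intensity
    (to the surviving base peak) >= the floor, within the most intense
    top_n_cap peaks."""
    base = query.base_peak_intensity()
    if base <= 0:
        return []
    ranked = sorted(query.peaks, key=lambda p: (-p.intensity, p.mz))[: config.top_n_cap]
    return [p for p in ranked if p.intensity / base >= config.min_rel_intensity]


def ps(
    query: MsmsSpectrum,
    candidate: LibrarySpectrum,
    config: SearchConfig,
) -> ScoreDetail:
    """Probability subscore: PS = -log10 of the binomial upper tail of
    matching k of the top-n query peaks to the m annotated candidate peaks by
    chance. Returns the full ScoreDetail (without DPS filled in)."""
    m = candidate.annotated_count
    top = top_n_peaks(query, config)
    n = len(top)
    p = random_match_prob(config.pro_tol_da, config.mz_range)
    if m == 0 or n == 0:
        return ScoreDetail(n=n, k=0, m=m, p=p, P=0.0, dps=0.0, ps=0.0)
    P = elevate(p, m)
    pairs = match_peaks(top, candidate.annotated_peaks, config.fragment_tol)
    k = len(pairs)
    tail = binomial_tail(n, k, P)
    value = 0.0 if k == 0 else -math.log10(max(tail, 1e-300))
    return ScoreDetail(n=n, k=k, m=m, p=p, P=P, dps=0.0, ps=value)


def final_score(dps_value: float, ps_value: float) -> float:
    """The final match score: the product of DPS and PS."""
    return dps_value * ps_value


class LibraryIndex:
    """Precursor-mass index over library entries and glycan compositions."""

    def __init__(self, library: SpectralLibrary, glycan_db: Sequence[GlycanComposition]):
        self.entries = list(library.entries)
        self.glycans = list(glycan_db)
        self._lib_mass = np.array([e.precursor_neutral_mass for e in self.entries], dtype=float)
        self._glycan_mass = np.array([g.mass for g in self.glycans], dtype=float)

    def candidates(
        self, query_mass: float, precursor_tol_ppm: float
    ) -> List[Tuple[LibrarySpectrum, GlycanComposition, float]]:
        """All (library entry, glycan, ppm error) with |lib + glycan - query|
        within the precursor tolerance (ppm of the query mass)."""
        if len(self.entries) == 0 or len(self.glycans) == 0:
            return []
        delta = self._lib_mass[:, None] + self._glycan_mass[None, :] - query_mass
        window = precursor_tol_ppm * 1e-6 * query_mass
        rows, cols = np.nonzero(np.abs(delta) <= window)
        return [
            (self.entries[r], self.glycans[c], float(delta[r, c] / query_mass * 1e6))
            for r, c in zip(rows.tolist(), cols.tolist())
        ]


def select_candidates(
    query: MsmsSpectrum,
    library: SpectralLibrary,
    glycan_db: Sequence[GlycanComposition],
    precursor_tol_ppm: float,
) -> List[Tuple[LibrarySpectrum, GlycanComposition]]:
    """Convenience wrapper returning the open-search candidate pairs for one
    query (targets and decoys both eligible)."""
    index = LibraryIndex(library, glycan_db)
    mass = query.precursor_neutral_mass
    if mass is None:
        return []
    return [(e, g) for e, g, _ in index.candidates(mass, precursor_tol_ppm)]


def _tie_hash(query_id: str, candidate: LibrarySpectrum, glycan: GlycanComposition) -> int:
    text = f"{query_id}|{candidate.peptide}|{candidate.charge}|{glycan}|{int(candidate.is_decoy)}"
    return int.from_bytes(hashlib.md5(text.encode()).digest()[:8], "big")


def _rank_key(gpsm: Gpsm) -> Tuple:
    return (
        -gpsm.score,
        abs(gpsm.precursor_error_ppm),
        _tie_hash(gpsm.query_id, gpsm.library, gpsm.glycan),
        gpsm.is_decoy,
        gpsm.library.peptide,
        str(gpsm.glycan),
    )


def search_spectrum(
    query: MsmsSpectrum,
    index: LibraryIndex,
    config: SearchConfig,
) -> List[Gpsm]:
    """Score every candidate for one preprocessed query and return the ranked
    list (up to max_output_rank). The rank-1 entry is the reported GPSM unless
    its score is zero."""
    mass = query.precursor_neutral_mass
    if mass is None:
        return []
    scored: List[Gpsm] = []
    for entry, glycan, err_ppm in index.candidates(mass, config.precursor_tol_ppm):
        detail = ps(query, entry, config)
        detail.dps = dps(query, entry, config.fragment_tol)
        scored.append(
            Gpsm(
                query_id=query.id,
                library=entry,
                glycan=glycan,
                charge=query.charge,
                precursor_error_ppm=err_ppm,
                detail=detail,
            )
        )
    scored.sort(key=_rank_key)
    scored = scored[: config.max_output_rank]
    for rank, gpsm in enumerate(scored, start=1):
        gpsm.rank = rank
    return scored


@dataclass
class SearchResult:
    """Batch search output: best matches, full ranked lists, and counters."""

    best: List[Gpsm] = field(default_factory=list)
    ranked: Dict[str, List[Gpsm]] = field(default_factory=dict)
    rejected: Dict[str, int] = field(default_factory=dict)
    n_queries: int = 0
    n_searched: int = 0


def search_all(
    queries: Sequence[MsmsSpectrum],
    library: SpectralLibrary,
    glycan_db: Sequence[GlycanComposition],
    config: Optional[SearchConfig] = None,
    oxonium_table: Optional[OxoniumTable] = None,
    preprocessed: bool = False,
) -> SearchResult:
    """Preprocess and search every query spectrum. Deterministic given inputs
    and config. Spectra without a charge, or failing the diagnostic-ion gate,
    are counted in ``rejected``."""
    config = config or SearchConfig()
    table = oxonium_table if oxonium_table is not None else OxoniumTable.default()
    index = LibraryIndex(library, glycan_db)
    result = SearchResult(n_queries=len(queries))
    for query in queries:
        if query.charge is None:
            result.rejected[REASON_MISSING_CHARGE] = result.rejected.get(REASON_MISSING_CHARGE, 0) + 1
            continue
        if preprocessed:
            clean = query
        else:
            pre = preprocess_query(query, config, table)
            if not pre.passed:
                result.rejected[pre.reason] = result.rejected.get(pre.reason, 0) + 1
                continue
            clean = pre.spectrum
        result.n_searched += 1
        ranked = search_spectrum(clean, index, config)
        if ranked:
            result.ranked[query.id] = ranked
            if ranked[0].score > 0:
                result.best.append(ranked[0])
    return result


def gpsms_to_dataframe(gpsms: Sequence[Gpsm]):
    """Render GPSMs as the output table (one row per match)."""
    import pandas as pd

    rows = []
    for g in gpsms:
        rows.append(
            {
                "query_id": g.query_id,
                "peptide": g.library.peptide,
                "modifications": format_modifications(g.library.modifications),
                "glycan": str(g.glycan),
                "charge": g.charge,
                "library_charge": g.library.charge,
                "precursor_error_ppm": round(g.precursor_error_ppm, 4),
                "dps": round(g.detail.dps, 6),
                "ps": round(g.detail.ps, 6),
                "score": round(g.score, 6),
                "n": g.detail.n,
                "k": g.detail.k,
                "m": g.detail.m,
                "decoy": int(g.is_decoy),
                "rank": g.rank,
            }
        )
    columns = [
        "query_id", "peptide", "modifications", "glycan", "charge", "library_charge",
        "precursor_error_ppm", "dps", "ps", "score", "n", "k", "m", "decoy", "rank",
    ]
    return pd.DataFrame(rows, columns=columns)
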