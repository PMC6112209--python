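"""Target-decoy FDR estimation and the two FDR-validation diagnostics.

FDR at a score threshold is estimated as D/T, the ratio of decoy to target
matches at or above the threshold. For filtering, the running D/T is
monotonized from the bottom of the score-sorted list into a per-GPSM q-value,
and targets with q <= level are reported (decoys are excluded from the
report).

Two diagnostics probe whether incorrect matches really split evenly between
targets and decoys: the target/decoy composition per rank of the retained
candidate lists, and a null search of falsified spectra in which every
non-oxonium peak is shifted by +10 m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .params import Tolerance
from .preprocess import OxoniumTable
from .search import Gpsm
from .spectra import MsmsSpectrum, Peak


@dataclass
class FdrResult:
    """Outcome of target-decoy filtering at one report level."""

    level: float
    threshold: Optional[float]
    n_targets_total: int
    n_decoys_total: int
    T: int
    D: int
    fdr: float
    table: pd.DataFrame = field(repr=False, default=None)


def _sorted_gpsms(gpsms: Sequence[Gpsm]) -> List[Gpsm]:
    return sorted(gpsms, key=lambda g: (-g.score, g.is_decoy, g.query_id))


def estimate_fdr(gpsms: Sequence[Gpsm], level: float = 0.01) -> Tuple[FdrResult, List[Gpsm]]:
    """Estimate FDR = D/T over rank-1 GPSMs and return the targets accepted
    at the requested level.

    The returned table holds, for every GPSM in descending score order, the
    cumulative T and D, the raw D/T at that threshold, and the monotonized
    q-value. Ties at the cutoff are all included if their shared q passes.
    """
    ordered = _sorted_gpsms(gpsms)
    n_targets = sum(1 for g in ordered if not g.is_decoy)
    n_decoys = len(ordered) - n_targets
    if n_targets == 0:
        import warnings

        warnings.warn("no target GPSMs; empty FDR result")
        empty = pd.DataFrame(columns=["query_id", "score", "decoy", "T", "D", "fdr", "q_value"])
        return FdrResult(level, None, 0, n_decoys, 0, 0, 0.0, empty), []

    T = D = 0
    cum_T: List[int] = []
    cum_D: List[int] = []
    for g in ordered:
        if g.is_decoy:
            D += 1
        else:
            T += 1
        cum_T.append(T)
        cum_D.append(D)

    # raw FDR is a function of the score threshold, so it is evaluated at the
    # bottom of each tied-score group and shared by the whole group
    raw_fdr = [0.0] * len(ordered)
    i = len(ordered) - 1
    while i >= 0:
        j = i
        while j - 1 >= 0 and ordered[j - 1].score == ordered[i].score:
            j -= 1
        value = cum_D[i] / cum_T[i] if cum_T[i] > 0 else float("inf")
        for idx in range(j, i + 1):
            raw_fdr[idx] = value
        i = j - 1

    q_values = list(raw_fdr)
    for i in range(len(q_values) - 2, -1, -1):
        q_values[i] = min(q_values[i], q_values[i + 1])

    accepted: List[Gpsm] = []
    threshold = None
    for g, q in zip(ordered, q_values):
        if q <= level:
            threshold = g.score
            if not g.is_decoy:
                accepted.append(g)

    idx = max(
        (i for i, q in enumerate(q_values) if q <= level),
        default=None,
    )
    T_cut = cum_T[idx] if idx is not None else 0
    D_cut = cum_D[idx] if idx is not None else 0

    table = pd.DataFrame(
        {
            "query_id": [g.query_id for g in ordered],
            "score": [g.score for g in ordered],
            "decoy": [int(g.is_decoy) for g in ordered],
            "T": cum_T,
            "D": cum_D,
            "fdr": raw_fdr,
            "q_value": q_values,
        }
    )
    result = FdrResult(
        level=level,
        threshold=threshold,
        n_targets_total=n_targets,
        n_decoys_total=n_decoys,
        T=T_cut,
        D=D_cut,
        fdr=(D_cut / T_cut) if T_cut else 0.0,
        table=table,
    )
    return result, accepted


def rank_distribution(
    ranked: Dict[str, List[Gpsm]],
    max_rank: int = 10,
) -> pd.DataFrame:
    """Per-rank target/decoy counts and target fractions over the retained
    candidate lists (all matches, no score filtering)."""
    counts = {r: [0, 0] for r in range(1, max_rank + 1)}
    for gpsms in ranked.values():
        for g in gpsms:
            if 1 <= g.rank <= max_rank:
                counts[g.rank][int(g.is_decoy)] += 1
    rows = []
    for rank in range(1, max_rank + 1):
        t, d = counts[rank]
        total = t + d
        rows.append(
            {
                "rank": rank,
                "targets": t,
                "decoys": d,
                "total": total,
                "target_fraction": (t / total) if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def falsify_spectra(
    spectra: Sequence[MsmsSpectrum],
    shift: float = 10.0,
    oxonium_table: Optional[OxoniumTable] = None,
    fragment_tol: Optional[Tolerance] = None,
) -> List[MsmsSpectrum]:
    """Create a null data set by adding ``shift`` m/z units to every peak
    except oxonium ions (peaks within the fragment tolerance of a table
    entry); precursors are left unchanged."""
    table = oxonium_table if oxonium_table is not None else OxoniumTable.default()
    tol = fragment_tol if fragment_tol is not None else Tolerance(20.0, "ppm")
    out = []
    for spectrum in spectra:
        peaks = []
        for peak in spectrum.peaks:
            if any(tol.within(peak.mz, ox) for ox in table.mz_values):
                peaks.append(peak)
            else:
                peaks.append(Peak(peak.mz + shift, peak.intensity, peak.annotation))
        out.append(spectrum.with_peaks(peaks))
    return out


@dataclass
class NullValidation:
    """Target fraction of rank-1 matches with an exact binomial CI."""

    n: int
    targets: int
    target_fraction: float
    ci_low: float
    ci_high: float
    confidence: float

    @property
    def consistent_with_half(self) -> bool:
        return self.ci_low <= 0.5 <= self.ci_high


def validate_null(
    ranked: Dict[str, List[Gpsm]],
    confidence: float = 0.99,
) -> Optional[NullValidation]:
    """Summarize the rank-1 target fraction of a (typically falsified-spectra)
    search with an exact binomial confidence interval. Returns None when there
    are no rank-1 matches."""
    rank1 = [gpsms[0] for gpsms in ranked.values() if gpsms]
    n = len(rank1)
    if n == 0:
        return None
    targets = sum(1 for g in rank1 if not g.is_decoy)
    ci = binomtest(targets, n).proportion_ci(confidence_level=confidence, method="exact")
    return NullValidation(
        n=n,
        targets=targets,
        target_fraction=targets / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        confidence=confidence,
    )
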