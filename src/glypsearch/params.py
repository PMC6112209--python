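"""Tolerances and run configuration for library construction and search."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional


@dataclass(frozen=True)
class Tolerance:
    """A mass tolerance, either relative (``ppm``) or absolute (``da``)."""

    value: float
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if self.unit not in ("ppm", "da"):
            raise ValueError(f"tolerance unit must be 'ppm' or 'da', got {self.unit!r}")
        if self.value <= 0:
            raise ValueError("tolerance must be positive")

    def da_at(self, mz: float) -> float:
        """Absolute half-window (Da) at a given m/z."""
        return self.value * 1e-6 * mz if self.unit == "ppm" else self.value

    def within(self, observed: float, reference: float) -> bool:
        return abs(observed - reference) <= self.da_at(reference)

    def __str__(self) -> str:
        return f"{self.value:g} {self.unit}"

    @classmethod
    def parse(cls, text: str) -> "Tolerance":
        parts = str(text).split()
        if len(parts) == 1:
            return cls(float(parts[0]), "ppm")
        return cls(float(parts[0]), parts[1].lower())


@dataclass
class SearchConfig:
    """All tolerances, defaults and switches of the open library search.

    Defaults follow the published workflow: 10 ppm precursor and 20 ppm
    fragment tolerances, an MS/MS m/z range of 2,000 Da, at most 6 peaks kept
    per 100 Th, top-12 query peaks with a 0.05 relative-intensity floor for
    the probability score, and a 1% FDR report level.
    """

    precursor_tol_ppm: float = 10.0
    fragment_tol: Tolerance = field(default_factory=lambda: Tolerance(20.0, "ppm"))
    mz_range: float = 2000.0
    top_n_cap: int = 12
    min_rel_intensity: float = 0.05
    max_peaks_per_window: int = 6
    window_width: float = 100.0
    max_isotope_charge: int = 2
    max_output_rank: int = 10
    fdr_level: float = 0.01
    diagnostic_mz: float = 138.054953

    @property
    def pro_tol_da(self) -> float:
        """The single absolute product tolerance (Da) entering the random-match
        probability p = 2*pro_tol/mz_range. A ppm fragment tolerance is
        converted at the reference m/z of mz_range/2."""
        return self.fragment_tol.da_at(self.mz_range / 2.0)


@dataclass
class LibraryBuildConfig:
    """Configuration of spectral-library construction."""

    #: Weight of the theoretical spectrum in the theta-merge (0 = purely
    #: experimental consensus, 1 = purely theoretical b/y + Y ions).
    theta: float = 0.5
    #: Name/delta of the deglycosylation artifact to strip at glycosites:
    #: "Deamidation" (PNGase F) or "HexNAc" (HCD-pd-MS3 stub).
    modification_remove: str = "Deamidation"
    modification_remove_delta: Optional[float] = None
    #: Tolerance used both for consensus merging across replicates and for
    #: pairing consensus peaks with theoretical fragment ions.
    fragment_tol: Tolerance = field(default_factory=lambda: Tolerance(0.02, "da"))
    #: Relative intensity of the injected Y0..Y5 ions (fraction of base peak).
    y_ion_relative_intensity: float = 0.40
    include_cys_sequon: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


def config_to_text(config) -> str:
    """Render a config dataclass as flat ``key = value`` lines."""
    lines = []
    for f in fields(config):
        lines.append(f"{f.name} = {getattr(config, f.name)}")
    return "\n".join(lines) + "\n"
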