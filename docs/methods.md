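# Methods

## Problem and model

An intact N-linked glycopeptide fragmented by HCD yields three ion families:
glycan oxonium ions (low m/z, peptide-free), Y ions (the peptide backbone
retaining 0–k monosaccharides after glycosidic cleavage), and an attenuated
peptide b/y ladder. `glypsearch` treats identification as an open
spectral-library search: the peptide evidence is carried by a library of
deglycopeptide spectra, and the glycan is inferred from the precursor mass
difference, restricted to a database of plausible monosaccharide
compositions. Peptide and glycan are therefore assigned jointly to one
spectrum, and a single target-decoy FDR governs the pair.

All masses are monoisotopic and derived from atomic compositions at import
time (via pyteomics), never hard-coded: Hex C6H10O5, HexNAc C8H13NO5, Fuc
C6H10O4, NeuAc C11H17NO8, NeuGc C11H17NO9; `J` is an Asn known to carry a
glycan and has exactly the unmodified Asn residue mass, because the library
precursor represents the bare peptide and the glycan mass is added at
candidate-selection time.

## Library construction

1. **Grouping.** Identifications are grouped by (J-encoded sequence,
   modifications surviving artifact removal, charge). Only modifications at
   detected glycosites matching the configured `modification_remove`
   (Deamidation +0.984016 Da for PNGase F input, HexNAc +203.079373 Da for an
   HCD-pd-MS3 stub) are stripped; deamidations elsewhere are genuine and kept.
2. **Consensus.** Replicate peaks agreeing within the build fragment
   tolerance (default 0.02 Da) are merged with averaged m/z and intensity;
   peaks seen in only a subset of replicates are kept at their own intensity
   (information-preserving; the θ-merge dominates the final shape anyway).
3. **θ-merge.** The consensus (normalized to base peak 1, weighted 1−θ) and
   the theoretical b/y spectrum (uniform intensity, weighted θ; charges 1+
   and 2+ for precursors ≥ 2+) are superimposed; matched peaks add their
   weighted intensities and sit at the *theoretical* m/z, so library fragment
   positions are exact regardless of the instrument that produced the input
   (e.g. 0.5 Da MS3 fragments). Default θ = 0.5, an equal blend; θ is a
   config field with the limits θ=0 (purely experimental intensities at
   theoretical positions) and θ=1 (purely theoretical) both exercised in
   tests.
4. **Y-ion injection.** The six core ions Y0…Y5 (bare peptide, +HexNAc,
   +2HexNAc, +2HexNAc +1…3Hex — the N-glycan trimannosyl core) are appended
   at 40% relative intensity, at 1+ and (for 2+ or higher precursors) 2+.
   The 40% is relative to the final base peak: the spectrum is renormalized
   after injection, which is a no-op whenever any b/y or consensus peak is at
   1.0. The Y ladder is what lets a bare-peptide library spectrum explain a
   glycopeptide query.
5. **Decoys.** One decoy per target: the sequence is reversed with each
   sequon triplet held at its absolute position (so the glycopeptide motif
   survives), modifications travel with their residues, annotated b/y peaks
   are recomputed at decoy positions with intensities preserved, and Y plus
   unannotated peaks are byte-identical to the target. Precursor mass and
   charge are exactly the target's (same residue multiset). Palindromic edge
   cases (decoy = target) are counted in the log and kept.

## Query preprocessing

Order: diagnostic-ion gate → deisotoping → oxonium removal → density cap.

* The gate requires a peak within the fragment tolerance (ppm by default) of
  138.054953 Th (HexNAc internal fragment).
* Deisotoping is greedy left-to-right chain building at z ∈ {1, 2} with
  spacing 1.00235/z, requiring non-increasing intensity after the first
  isotope; the longest chain per starting peak wins and its non-monoisotopic
  members are removed. Simple, deterministic, and oracle-testable.
* The 25-entry oxonium table is reconstructed from monosaccharide fragment
  compositions (HexNAc and its five secondary fragments, Hex/Fuc/NeuAc/NeuGc
  with dehydrations, and the common di/trisaccharide ions up to
  NeuAc+Hex+HexNAc); it is user-replaceable via TSV for labs with their own
  curated list.
* The density cap keeps the 6 most intense peaks per fixed 100 Th bin
  anchored at 0 (ties to the lower m/z). It runs last so oxonium removal
  cannot free slots retroactively.

The gate consumes its own evidence (the diagnostic ion is itself stripped),
so the pipeline as a whole is idempotent only through its cleaning stages;
`preprocess_query(..., require_diagnostic=False)` re-runs those and is a
fixed point, which the tests assert.

## Scoring

DPS is the cosine similarity over one-to-one greedily matched peak pairs
(ascending |Δm/z| within the fragment tolerance), with norms over *all*
peaks of both spectra — unmatched intensity dilutes the score. PS is
−log₁₀ of the exact binomial upper tail of matching k of the top-n query
peaks (relative intensity ≥ 0.05 after preprocessing, n ≤ 12) to the
candidate's m annotated peaks by chance, with p = 2·pro_tol/mz_range
(mz_range 2000 Da; a ppm fragment tolerance is converted to the Da width at
the mid-range reference m/z of 1000). The base-10 logarithm makes PS read
like a −log₁₀ p-value. Annotated peaks are b/y *and* Y ions: the Y ladder is
injected precisely to be matched, so it participates in both m and k. The
tail is summed directly in floating point (≤ 13 positive terms; no
cancellation), and tests pin it to an exact rational enumeration at 1e-10.

The final score is DPS × PS; a rank-1 candidate with score 0 is not
reported. Candidate ordering is (score desc, |ppm error| asc, stable md5
content hash): the hash replaces any target-before-decoy preference so that
zero-score diagnostics (used by the FDR validation below) carry no
systematic flag bias. Charge is not required to match between query and
library (MS3-derived libraries legitimately differ); selection is purely
neutral-mass based. Multi-sequon peptides receive one composition for the
peptide as a whole — site localization is out of scope.

## FDR estimation and validation

FDR = D/T exactly (not (D+1)/T or D/(T+D)), evaluated per score threshold at
tied-score group boundaries, monotonized into q-values from the bottom of
the sorted list; targets with q ≤ level (default 1%) are reported and ties
at the cutoff stand or fall together. A brute-force threshold-sweep oracle
reproduces the accepted set exactly in tests.

Two diagnostics probe the estimator's premise that incorrect matches split
evenly between targets and decoys: the per-rank target/decoy composition of
the retained top-10 candidate lists, and a null search of falsified spectra
(every non-oxonium peak shifted +10 m/z, precursor untouched) whose rank-1
target fraction is summarized with an exact 99% binomial CI.

One caveat is structural: because each decoy shares its target's precursor
mass *and* Y0…Y5 ions, the paired decoy of a correctly identified query
typically outranks random candidates and lands at rank 2, and the same
target peptide with a neighboring glycan tends to occupy rank 3. At the
desk-scale candidate density of the synthetic benchmark these two ranks are
therefore measurably off the 50/50 line, while ranks 4–10 — and all ranks
for pure-noise queries, and rank 1 under falsification — behave as an even
coin flip. In very large libraries the random-candidate pool swamps the
paired decoy and the deep ranks flatten globally.

## Synthetic fixtures

The generator emulates, from one seeded `numpy` generator: tryptic-like
peptides (8–16 residues, C-terminal K/R, exactly one planted N-X-S/T
sequon), 2–3 deglycopeptide replicates per peptide (b/y ladder with the
deamidation artifact, detection probability 0.7, log-normal intensities
σ=0.4, 3 ppm mass jitter, ~2 noise peaks/100 Th), and query spectra whose
precursor is bare peptide + glycan (3 ppm jitter) with glycosite-free b/y
ions, a Y0…Y5 subset (detection 0.6), oxonium ions always including the
diagnostic, and noise. Pure-noise queries (50% of the set) share the
precursor-mass distribution but carry no fragment signal. The glycan
database is a deterministic 85-composition complex/high-mannose enumeration
(HexNAc 2–6, Hex 3–8, ±Fuc, ≤2 NeuAc) spanning the realistic mass range.

What the fixtures do **not** emulate: isotope envelopes and co-isolated
precursors (monoisotopic-assignment errors), retention time, glycan
structural isomers, Y-ion intensity correlation with glycan size, or
instrument-specific noise. Passing benchmarks therefore demonstrate the
correctness and calibration of the search machinery under its stated
assumptions, not instrument-level performance on real data.

Default benchmark scale — 200 peptides × 85 glycans, 500 true + 500 noise
queries — was chosen as the smallest set giving stable rank statistics
(hundreds of entries per deep rank) while a full run, including the
falsified-spectra null and a determinism re-run, completes in well under a
minute.

## Numerical and degenerate-input choices

* Tolerances are `Tolerance(value, unit)` with unit ppm or Da; ppm windows
  are evaluated at the reference (heavier) peak.
* Empty spectra: DPS = 0 by convention; n = 0 or m = 0 gives PS = 0; an
  all-oxonium spectrum survives preprocessing as an empty peak list and can
  match nothing.
* Zero-intensity MGF peaks are dropped at parse; spectra without CHARGE are
  kept but excluded from search with a counter.
* The binomial tail is floored at 1e-300 before the log as an overflow guard
  (unreachable for n ≤ 12 at realistic P).
* Determinism: no iteration over unordered sets; tie-breaking uses md5, not
  Python's salted `hash`; identical inputs give byte-identical output
  tables.

## Known limitations

Site localization among multiple sequons, glycan topology, CID/MS3 pairing
strategies, and precursor monoisotopic-peak correction are out of scope; the
identification-table schema is a package-defined TSV stand-in for search
engine exports; and the 25-ion oxonium list is a composition-derived default
rather than a transcription of any lab's curated table (supply your own TSV
to override).
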