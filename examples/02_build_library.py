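"""Build an optimized target+decoy spectral library from deglycopeptide
identifications and their replicate spectra (synthetic here)."""

import numpy as np

from glypsearch import build_library
from glypsearch.simulate import FixtureConfig, generate_library_spectra, generate_peptides

config = FixtureConfig(n_peptides=5, seed=3)
rng = np.random.default_rng(config.seed)
peptides = generate_peptides(config, rng)
identifications, spectra = generate_library_spectra(peptides, config, rng)
print(f"{len(identifications)} deglycopeptide PSMs over {len(peptides)} peptides")

library = build_library(identifications, spectra)
print(f"library: {len(library.targets)} targets + {len(library.decoys)} decoys\n")

for target, decoy in zip(library.targets, library.decoys):
    y_ions = sum(1 for p in target.peaks if p.annotation and p.annotation.startswith("Y"))
    print(
        f"{target.peptide:>18} ({target.charge}+, {target.precursor_neutral_mass:9.4f} Da, "
        f"m={target.annotated_count:2d}, {y_ions} Y peaks)  <->  decoy {decoy.peptide}"
    )
# Each target peptide is J-encoded at its glycosite (the deamidation artifact
# was stripped, so the precursor is the bare peptide). The decoy reverses the
# sequence around the fixed sequon and shares the target's exact precursor
# mass, charge, Y0..Y5 ions and unannotated peaks — only b/y positions move.
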