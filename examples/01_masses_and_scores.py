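"""Glycan mass bookkeeping and the score arithmetic on a toy match.

Builds a two-peak query and a two-peak library spectrum, then walks through
every ingredient of the final score by hand-checkable arithmetic.
"""

from glypsearch import (
    GlycanComposition,
    LibrarySpectrum,
    MsmsSpectrum,
    Peak,
    Tolerance,
    binomial_tail,
    dps,
    elevate,
    final_score,
    glycan_mass,
    random_match_prob,
)

# --- glycan compositions -----------------------------------------------------
comp = GlycanComposition.from_string("H5N4F1")
print(f"H5N4F1 mass: {comp.mass:.6f} Da")
print(f"core H3N2 mass: {glycan_mass({'Hex': 3, 'HexNAc': 2}):.6f} Da")
# These are sums of monosaccharide residue masses; the search adds them to a
# library peptide mass to explain a query precursor.

# --- the two subscores -------------------------------------------------------
tol = Tolerance(0.02, "da")
query = MsmsSpectrum("q", 800.0, 2, [Peak(100.0, 1.0), Peak(200.0, 2.0)])
library = LibrarySpectrum("T0", "AJGTK", (), 2, 1000.0, (2,),
                          [Peak(100.0, 2.0, "b1+1"), Peak(300.0, 1.0, "b2+1")])

d = dps(query, library, tol)
print(f"DPS = {d}")  # 2 / (sqrt(5) * sqrt(5)) = 0.4: cosine similarity of matched intensity

p = random_match_prob(0.02, 2000.0)
P = elevate(p, 50)
print(f"p = {p}  (chance a peak pair matches within 0.02 Da over a 2000 Da range)")
print(f"P = {P:.6e}  (chance one query peak matches any of m=50 annotated peaks)")

tail = binomial_tail(12, 6, P)
ps_value = -__import__("math").log10(tail)
print(f"PS for k=6 of n=12 top peaks matched: {ps_value:.2f}")
print(f"final score = DPS x PS = {final_score(d, ps_value):.3f}")
# PS behaves like -log10 of a p-value: 6 matched top peaks at P ~ 1e-3 is
# overwhelming evidence against a chance match.
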