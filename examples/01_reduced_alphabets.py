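"""Reduced amino-acid alphabets: re-express a peptide in 5 or 7 groups.

Reduced alphabets collapse the 20 amino acids into groups sharing a
property (hydropathy, conformational preference), trading residue identity
for statistical robustness of downstream count features.
"""

from ampfeat import load_alphabet, reduce_sequence

peptide = "MKVLATTRSGYEILTNPQKWFHDECVAGIRS"  # a 31-mer window

for name in ("no_reduction", "hydro", "conform"):
    alpha = load_alphabet(name)
    rep = reduce_sequence(peptide, alpha)
    print(f"{name:13s} (k={alpha.size:2d}): {' '.join(rep.tokens)}")

# Each line is the same peptide position-by-position; under "hydro" every
# symbol H_1..H_5 is a bin of the Kyte-Doolittle hydropathy scale, so runs
# of the same symbol mark stretches of similar hydrophobicity.
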