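"""Monogram counts, offset co-occurrence matrices and texture statistics.

The co-occurrence matrix G^delta counts symbol pairs separated by delta
positions; its five texture statistics compress the k x k matrix into
scalars describing how concentrated, random or diagonal-heavy the pair
distribution is.
"""

import numpy as np

from ampfeat import (
    cooccurrence_matrix,
    load_alphabet,
    monogram_counts,
    reduce_sequence,
    texture_features,
)

peptide = "MKVLATTRSGYEILTNPQKWFHDECVAGIRS"
hydro = load_alphabet("hydro")
rep = reduce_sequence(peptide, hydro)

mono = monogram_counts(rep)
print("monogram fractions:", dict(zip(hydro.symbols, np.round(mono.values, 3))))
print("sum =", mono.values.sum())  # always 1: it is a composition

for delta in (1, 3):
    mat = cooccurrence_matrix(rep, delta)
    tf = texture_features(mat)
    print(f"\ndelta={delta}: {mat.pair_count} pairs, matrix sum {mat.values.sum():.3f}")
    print(f"  energy={tf.energy:.4f} entropy={tf.entropy:.3f} bits "
          f"homogeneity={tf.homogeneity:.4f} contrast={tf.contrast:.3f} "
          f"dissimilarity={tf.dissimilarity:.3f}")

# Higher entropy means pair usage is spread evenly over the 25 cells;
# high homogeneity/low contrast means most pairs join residues from the
# same or adjacent hydropathy groups.
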