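"""Skip-gram sequence embeddings (ProtVec on the standard alphabet).

N-grams of a sequence corpus are treated as words and embedded with
skip-gram; a peptide's embedding is the sum of its overlapping n-gram
vectors, giving a fixed-length representation independent of length.
"""

import numpy as np

from ampfeat import (
    build_corpus,
    embed_sequence,
    generate_synthetic,
    load_alphabet,
    reduce_sequence,
    train_embedding,
)

records = generate_synthetic(30, 30, seed=0)
alpha = load_alphabet("no_reduction")
reps = [reduce_sequence(r.sequence, alpha, r.id) for r in records]

corpus = build_corpus(reps, ngram_size=3)
print(f"corpus: {len(corpus)} documents from {len(reps)} peptides")

model = train_embedding(corpus, dimension=50, alphabet=alpha, ngram_size=3,
                        epochs=3, seed=0)
print(f"vocabulary: {len(model.vocabulary)} trigrams, {model.dimension}-dim vectors")

vec = embed_sequence(reps[0], model)
print(f"embedding of {records[0].id}: length {vec.shape[0]}, "
      f"norm {np.linalg.norm(vec):.3f}")
# The 50 numbers are the summed trigram vectors; peptides sharing many
# trigrams land near each other in this space.
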