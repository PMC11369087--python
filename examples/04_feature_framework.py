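"""The feature-extraction framework: representations x feature types x offsets.

A FeatureSpec names which alphabets to use, which feature families to
compute and at which pair offsets; the framework concatenates every block
into one named vector.  The worked configuration below — two
representations, monogram counts + texture features, offsets 1 and 3 —
yields (20 + 5) counts + 5 stats x 2 reps x 2 offsets = 45 features.
"""

from ampfeat import FeatureSpec, extract_matrix, feature_dimension, feature_names, generate_synthetic

spec = FeatureSpec(
    representations=("no_reduction", "hydro"),
    feature_types=("counts", "tfeat"),
    offsets=(1, 3),
)
print("total features:", feature_dimension(spec))  # 45

names = feature_names(spec)
print("first five:", names[:5], "... last two:", names[-2:])

records = generate_synthetic(10, 10, seed=1)
matrix = extract_matrix(records, spec)
print("feature matrix:", matrix.values.shape)  # 20 peptides x 45 features
print("row ids:", matrix.row_ids[:3], "... labels sum:", int(matrix.labels.sum()))
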