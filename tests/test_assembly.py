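"""The feature-extraction framework: dimensions, names, block-wise assembly."""

import numpy as np
import pytest

from ampfeat.alphabet import load_alphabet, reduce_sequence
from ampfeat.assembly import (
    FeatureSpec,
    extract_features,
    extract_matrix,
    feature_dimension,
    feature_names,
)
from ampfeat.composition import bigram_vector, cooccurrence_matrix, monogram_counts
from ampfeat.data import generate_synthetic
from ampfeat.texture import texture_features

# every printed configuration/feature-count pair from the result tables
TABLE_CONFIGS = [
    (("no_reduction", "hydro"), ("counts", "tfeat"), (1, 3), 45),
    (("conform", "no_reduction", "hydro"), ("counts", "mat"), (1, 3), 980),
    (("conform", "no_reduction"), ("mat",), (1, 3), 898),
    (("no_reduction", "hydro"), ("counts", "mat"), (1, 3), 875),
    (("conform", "no_reduction"), ("counts", "mat"), (1, 2, 3), 1374),
    (("no_reduction",), ("counts", "mat"), (1, 2), 820),
    (("no_reduction", "hydro"), ("tfeat", "pro2vec"), (3,), 360),
    (("conform", "no_reduction"), ("counts",), (1,), 27),
    (("no_reduction",), ("counts", "tfeat", "pro2vec"), (1,), 75),
    (("no_reduction", "hydro"), ("counts", "tfeat"), (3,), 35),
]


@pytest.mark.parametrize("reps,types,offsets,expected", TABLE_CONFIGS)
def test_dimension_arithmetic(reps, types, offsets, expected):
    spec = FeatureSpec(reps, types, offsets)
    assert feature_dimension(spec) == expected
    assert len(feature_names(spec)) == expected


def test_empty_feature_types_give_zero_dimension():
    assert feature_dimension(FeatureSpec(("no_reduction",), ())) == 0


def test_duplicate_spec_entries_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        FeatureSpec(("hydro", "hydro"), ("counts",))
    with pytest.raises(ValueError, match="unknown feature types"):
        FeatureSpec(("hydro",), ("glcm",))
    with pytest.raises(ValueError, match="positive"):
        FeatureSpec(("hydro",), ("mat",), (0,))


def test_monogram_feature_names_are_bare_symbols():
    names = feature_names(FeatureSpec(("no_reduction", "hydro"), ("counts",)))
    assert "K" in names and "H_2" in names
    assert len(names) == len(set(names))


def test_bigram_feature_names_use_pair_offset_convention():
    names = feature_names(FeatureSpec(("hydro",), ("mat",), (1,)))
    assert "H_2H_2(1)" in names
    assert names[0] == "H_1H_1(1)"


def test_texture_and_embedding_names():
    spec = FeatureSpec(("no_reduction",), ("tfeat", "pro2vec"), (2,))
    names = feature_names(spec)
    assert "no_reduction:energy(2)" in names
    assert "no_reduction:p2v_0" in names and "no_reduction:p2v_49" in names


def test_counts_and_pro2vec_are_offset_independent():
    a = FeatureSpec(("hydro",), ("counts",), (1,))
    b = FeatureSpec(("hydro",), ("counts",), (1, 2, 3))
    assert feature_dimension(a) == feature_dimension(b) == 5
    assert feature_names(a) == feature_names(b)


def test_feature_type_order_is_canonical_regardless_of_input_order():
    a = FeatureSpec(("hydro",), ("tfeat", "counts", "mat"), (1,))
    b = FeatureSpec(("hydro",), ("counts", "mat", "tfeat"), (1,))
    assert a.feature_types == b.feature_types == ("counts", "mat", "tfeat")
    assert feature_names(a) == feature_names(b)


def test_extract_concatenates_independent_blocks(random_31mer):
    """The assembled vector equals the concatenation of blocks computed directly."""
    spec = FeatureSpec(("no_reduction", "hydro"), ("counts", "mat", "tfeat"), (1, 3))
    vec = extract_features(random_31mer, spec)
    blocks = []
    for rep_name in ("no_reduction", "hydro"):
        alpha = load_alphabet(rep_name)
        rs = reduce_sequence(random_31mer, alpha)
        blocks.append(monogram_counts(rs).values)
        for d in (1, 3):
            blocks.append(bigram_vector(cooccurrence_matrix(rs, d)))
        for d in (1, 3):
            blocks.append(texture_features(cooccurrence_matrix(rs, d)).as_array())
    np.testing.assert_allclose(vec, np.concatenate(blocks))


def test_first_block_equals_monogram_counts(random_31mer, no_reduction):
    spec = FeatureSpec(("no_reduction",), ("counts",))
    vec = extract_features(random_31mer, spec)
    rs = reduce_sequence(random_31mer, no_reduction)
    np.testing.assert_allclose(vec, monogram_counts(rs).values)


def test_980_feature_vector_count_blocks_sum_to_one(random_31mer):
    spec = FeatureSpec(("conform", "no_reduction", "hydro"), ("counts", "mat"), (1, 3))
    vec = extract_features(random_31mer, spec)
    assert vec.shape == (980,)
    names = feature_names(spec)
    # each monogram and each bigram block is separately normalized
    start = 0
    for rep_name in ("conform", "no_reduction", "hydro"):
        k = load_alphabet(rep_name).size
        assert vec[start : start + k].sum() == pytest.approx(1.0)
        start += k
        for _ in (1, 3):
            assert vec[start : start + k * k].sum() == pytest.approx(1.0)
            start += k * k
    assert start == len(names) == 980


def test_extraction_is_deterministic(random_31mer):
    spec = FeatureSpec(("conform",), ("counts", "mat", "tfeat"), (1, 2))
    a = extract_features(random_31mer, spec)
    b = extract_features(random_31mer, spec)
    np.testing.assert_array_equal(a, b)


def test_pro2vec_without_model_errors(random_31mer):
    spec = FeatureSpec(("no_reduction",), ("pro2vec",))
    with pytest.raises(ValueError, match="embedding model"):
        extract_features(random_31mer, spec)


def test_extract_matrix_shape_and_order():
    records = generate_synthetic(5, 5, seed=3)
    spec = FeatureSpec(("no_reduction", "hydro"), ("counts", "tfeat"), (1, 3))
    matrix = extract_matrix(records, spec)
    assert matrix.values.shape == (10, 45)
    assert matrix.row_ids == [r.id for r in records]
    np.testing.assert_array_equal(matrix.labels, [r.label for r in records])
    # shuffled dataset: same rows, reordered
    shuffled = records[::-1]
    m2 = extract_matrix(shuffled, spec)
    np.testing.assert_allclose(m2.values, matrix.values[::-1])


def test_matrix_column_K_is_lysine_fraction():
    records = generate_synthetic(8, 8, seed=9)
    spec = FeatureSpec(("no_reduction",), ("counts",))
    matrix = extract_matrix(records, spec)
    col = matrix.values[:, matrix.feature_names.index("K")]
    expected = [r.sequence.count("K") / len(r.sequence) for r in records]
    np.testing.assert_allclose(col, expected)


def test_extract_matrix_reports_offending_id():
    class Bad:
        id = "oops"
        sequence = "ACDX"
        label = 0

    spec = FeatureSpec(("no_reduction",), ("counts",))
    with pytest.raises(ValueError, match="oops"):
        extract_matrix([Bad()], spec)


def test_spec_json_roundtrip():
    spec = FeatureSpec(("no_reduction", "hydro"), ("counts", "pro2vec"), (1, 3))
    again = FeatureSpec.from_json_dict(spec.to_json_dict())
    assert again == spec
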