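"""The feature-extraction framework: (representations, feature types, offsets) -> named vector.

A :class:`FeatureSpec` is the framework's parameter triple.  Each selected
representation is processed independently: the sequence is reduced, then
each selected feature family is computed — monogram counts once, bigram
(flattened co-occurrence) and texture blocks once per offset, a Pro2Vec
embedding once — and everything is concatenated in a fixed canonical order
(representation-major; feature types in the order counts, mat, tfeat,
pro2vec; then offsets; then the within-block index).

Feature naming follows the field's conventions: monograms by their symbol
("K", "H_2"), bigrams as "AB(δ)" (e.g. "H_2H_2(1)"), texture statistics as
"<rep>:<stat>(δ)", embedding components as "<rep>:p2v_<i>".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import Alphabet, load_alphabet, reduce_sequence
from .composition import bigram_vector, cooccurrence_matrix, monogram_counts
from .embedding import EmbeddingModel, embed_sequence
from .texture import TEXTURE_STAT_NAMES, texture_features

__all__ = [
    "FEATURE_TYPES",
    "FeatureSpec",
    "FeatureMatrix",
    "feature_dimension",
    "feature_names",
    "extract_features",
    "extract_matrix",
]

#: Canonical feature-type order; tokens match the result tables' vocabulary.
FEATURE_TYPES: tuple[str, ...] = ("counts", "mat", "tfeat", "pro2vec")

#: Feature families whose output depends on the offset list.
_OFFSET_DEPENDENT = ("mat", "tfeat")


@dataclass(frozen=True)
class FeatureSpec:
    """Parameter triple of the framework plus per-representation embedding sizes.

    Parameters
    ----------
    representations
        Ordered alphabet names, e.g. ``("no_reduction", "hydro")``.
    feature_types
        Subset of ``("counts", "mat", "tfeat", "pro2vec")``; stored in
        canonical order regardless of input order.
    offsets
        Positive pair offsets δ for the co-occurrence families.
    embedding_config
        Per-representation ``(ngram_size, dimension)``; required when
        "pro2vec" is selected.  Defaults (3, 50) for "no_reduction" and
        (3, 300) for reduced alphabets are filled in if omitted.
    """

    representations: tuple[str, ...]
    feature_types: tuple[str, ...]
    offsets: tuple[int, ...] = (1,)
    embedding_config: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in (
            ("representations", self.representations),
            ("feature_types", self.feature_types),
            ("offsets", self.offsets),
        ):
            if len(set(values)) != len(values):
                raise ValueError(f"duplicate entries in {name}: {values}")
        unknown = set(self.feature_types) - set(FEATURE_TYPES)
        if unknown:
            raise ValueError(f"unknown feature types {sorted(unknown)}; valid: {FEATURE_TYPES}")
        if any(d < 1 for d in self.offsets):
            raise ValueError(f"offsets must be positive integers, got {self.offsets}")
        # canonical type order, independent of how the user listed them
        object.__setattr__(
            self,
            "feature_types",
            tuple(t for t in FEATURE_TYPES if t in self.feature_types),
        )
        if "pro2vec" in self.feature_types:
            cfg = dict(self.embedding_config)
            for rep in self.representations:
                if rep not in cfg:
                    cfg[rep] = (3, 50 if rep == "no_reduction" else 300)
            object.__setattr__(self, "embedding_config", cfg)

    def alphabets(self) -> dict[str, Alphabet]:
        return {rep: load_alphabet(rep) for rep in self.representations}

    def to_json_dict(self) -> dict:
        return {
            "representations": list(self.representations),
            "feature_types": list(self.feature_types),
            "offsets": list(self.offsets),
            "embedding_config": {k: list(v) for k, v in self.embedding_config.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "FeatureSpec":
        return cls(
            representations=tuple(d["representations"]),
            feature_types=tuple(d["feature_types"]),
            offsets=tuple(d.get("offsets", [1])),
            embedding_config={k: tuple(v) for k, v in d.get("embedding_config", {}).items()},
        )


@dataclass
class FeatureMatrix:
    """The classifier-facing table: rows = peptides, columns = named features."""

    feature_names: list[str]
    values: np.ndarray
    row_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match row_ids x feature_names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names are not unique")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names, index=self.row_ids)
        df.index.name = "id"
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _require_embedding_config(spec: FeatureSpec) -> None:
    if "pro2vec" in spec.feature_types:
        missing = [r for r in spec.representations if r not in spec.embedding_config]
        if missing:
            raise ValueError(f"pro2vec selected but no embedding_config for {missing}")


def feature_dimension(spec: FeatureSpec) -> int:
    """Closed-form total width of the feature vector for a spec.

    counts contributes k per representation; mat contributes k^2 per
    representation per offset; tfeat 5 per representation per offset;
    pro2vec the embedding dimension per representation.  Offsets do not
    affect counts or pro2vec.
    """
    _require_embedding_config(spec)
    dim = 0
    for rep in spec.representations:
        k = load_alphabet(rep).size
        for ftype in spec.feature_types:
            if ftype == "counts":
                dim += k
            elif ftype == "mat":
                dim += k * k * len(spec.offsets)
            elif ftype == "tfeat":
                dim += len(TEXTURE_STAT_NAMES) * len(spec.offsets)
            elif ftype == "pro2vec":
                dim += spec.embedding_config[rep][1]
    return dim


def feature_names(spec: FeatureSpec) -> list[str]:
    """Deterministic canonical names, in extraction order."""
    _require_embedding_config(spec)
    names: list[str] = []
    for rep in spec.representations:
        alpha = load_alphabet(rep)
        for ftype in spec.feature_types:
            if ftype == "counts":
                names.extend(alpha.symbols)
            elif ftype == "mat":
                for delta in spec.offsets:
                    names.extend(
                        f"{a}{b}({delta})" for a in alpha.symbols for b in alpha.symbols
                    )
            elif ftype == "tfeat":
                for delta in spec.offsets:
                    names.extend(f"{rep}:{stat}({delta})" for stat in TEXTURE_STAT_NAMES)
            elif ftype == "pro2vec":
                dim = spec.embedding_config[rep][1]
                names.extend(f"{rep}:p2v_{i}" for i in range(dim))
    if len(set(names)) != len(names):
        raise ValueError("feature name collision across representations")
    return names


def extract_features(
    sequence: str,
    spec: FeatureSpec,
    models: dict[str, EmbeddingModel] | None = None,
) -> np.ndarray:
    """Feature vector of one amino-acid sequence under a spec.

    ``models`` maps representation name to a trained embedding model and is
    required iff "pro2vec" is selected.  The output is the concatenation of
    the per-representation blocks in :func:`feature_names` order.
    """
    _require_embedding_config(spec)
    if "pro2vec" in spec.feature_types:
        models = models or {}
        missing = [r for r in spec.representations if r not in models]
        if missing:
            raise ValueError(f"pro2vec selected but no embedding model supplied for {missing}")
    blocks: list[np.ndarray] = []
    for rep in spec.representations:
        alpha = load_alphabet(rep)
        rep_seq = reduce_sequence(sequence, alpha)
        mats = {}
        if any(t in spec.feature_types for t in _OFFSET_DEPENDENT):
            mats = {d: cooccurrence_matrix(rep_seq, d) for d in spec.offsets}
        for ftype in spec.feature_types:
            if ftype == "counts":
                blocks.append(monogram_counts(rep_seq).values)
            elif ftype == "mat":
                blocks.extend(bigram_vector(mats[d]) for d in spec.offsets)
            elif ftype == "tfeat":
                blocks.extend(texture_features(mats[d]).as_array() for d in spec.offsets)
            elif ftype == "pro2vec":
                blocks.append(embed_sequence(rep_seq, models[rep]))
    return np.concatenate(blocks) if blocks else np.zeros(0)


def extract_matrix(
    dataset,
    spec: FeatureSpec,
    models: dict[str, EmbeddingModel] | None = None,
) -> FeatureMatrix:
    """Feature matrix for a dataset of peptide records.

    ``dataset`` is an iterable of objects with ``id``, ``sequence`` and
    optionally ``label`` attributes (see :mod:`ampfeat.data`).  Rows are in
    dataset order; any per-sequence failure aborts with the offending id.
    """
    names = feature_names(spec)
    rows, ids, labels = [], [], []
    have_labels = True
    for rec in dataset:
        try:
            rows.append(extract_features(rec.sequence, spec, models))
        except ValueError as exc:
            raise ValueError(f"feature extraction failed for record {rec.id!r}: {exc}") from exc
        ids.append(rec.id)
        lbl = getattr(rec, "label", None)
        if lbl is None:
            have_labels = False
        else:
            labels.append(lbl)
    values = np.vstack(rows) if rows else np.zeros((0, len(names)))
    return FeatureMatrix(
        feature_names=names,
        values=values,
        row_ids=ids,
        labels=np.asarray(labels) if have_labels and labels else None,
    )
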