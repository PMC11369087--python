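"""Monogram (composition) vectors and offset co-occurrence (bigram) matrices.

For a represented sequence S = [a_1, ..., a_n] over a k-symbol alphabet:

* the monogram vector is the per-symbol count normalized by n;
* the offset-δ co-occurrence matrix G^δ counts ordered pairs
  (a_t, a_{t+δ}) for t = 1..n−δ and is normalized by the total pair count
  n−δ; δ=1 is the usual adjacent-bigram (dipeptide) matrix;
* the δ-bigram feature vector is the row-major flattening of G^δ.

No pseudo-counts are used anywhere.  A sequence too short for an offset
(δ ≥ n) yields the all-zero matrix so a dataset-wide feature table keeps a
fixed width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import Alphabet, RepresentedSequence

__all__ = [
    "MonogramVector",
    "CooccurrenceMatrix",
    "monogram_counts",
    "cooccurrence_matrix",
    "bigram_vector",
]


@dataclass(frozen=True)
class MonogramVector:
    """Normalized symbol frequencies in ``alphabet.symbols`` order."""

    alphabet: Alphabet
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.alphabet.size,):
            raise ValueError("monogram vector length must equal alphabet size")


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalized δ-offset pair frequencies; row = first symbol of the pair."""

    alphabet: Alphabet
    offset: int
    values: np.ndarray
    pair_count: int

    def __post_init__(self) -> None:
        k = self.alphabet.size
        if self.values.shape != (k, k):
            raise ValueError("co-occurrence matrix must be k x k")


def monogram_counts(rep_seq: RepresentedSequence) -> MonogramVector:
    """Normalized monogram count vector; entries sum to 1.

    Raises on an empty sequence (no normalization possible).
    """
    n = len(rep_seq)
    if n == 0:
        raise ValueError("cannot compute monogram counts of an empty sequence")
    index = {s: i for i, s in enumerate(rep_seq.alphabet.symbols)}
    counts = np.zeros(rep_seq.alphabet.size)
    for tok in rep_seq.tokens:
        counts[index[tok]] += 1
    return MonogramVector(alphabet=rep_seq.alphabet, values=counts / n)


def cooccurrence_matrix(rep_seq: RepresentedSequence, offset: int) -> CooccurrenceMatrix:
    """Normalized co-occurrence matrix G^δ for a fixed positional offset.

    Entry (i, j) is the fraction of positions t with a_t = p_i and
    a_{t+δ} = p_j among the n−δ counted pairs.  If the sequence has no
    pair at this offset (δ ≥ n) the all-zero matrix is returned with
    ``pair_count`` 0.
    """
    if offset < 1:
        raise ValueError(f"offset must be a positive integer, got {offset}")
    alpha = rep_seq.alphabet
    index = {s: i for i, s in enumerate(alpha.symbols)}
    n = len(rep_seq)
    pair_count = max(0, n - offset)
    values = np.zeros((alpha.size, alpha.size))
    for t in range(pair_count):
        values[index[rep_seq.tokens[t]], index[rep_seq.tokens[t + offset]]] += 1
    if pair_count > 0:
        values /= pair_count
    return CooccurrenceMatrix(alphabet=alpha, offset=offset, values=values, pair_count=pair_count)


def bigram_vector(matrix: CooccurrenceMatrix) -> np.ndarray:
    """Row-major flattening [G_11, G_12, ..., G_kk] of a co-occurrence matrix."""
    return matrix.values.reshape(-1).copy()
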