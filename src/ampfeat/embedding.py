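"""Pro2Vec: skip-gram n-gram embeddings of (possibly reduced) sequences.

A sequence is tokenized into n-gram "words" and treated as a sentence; a
skip-gram model with negative sampling learns a vector per n-gram, and the
embedding of a sequence is the sum of the vectors of all its *overlapping*
n-grams.  On the standard 20-letter alphabet this is the ProtVec scheme
(default dimension 50); on a reduced alphabet it is RA2Vec (default
dimension 300).

Training corpora follow the shifted non-overlapping n-gram convention: a
sequence of length n contributes ``ngram_size`` documents, one per shift
offset 0..ngram_size-1, each listing the consecutive non-overlapping
n-grams starting at that shift (trailing residues shorter than n dropped).

The trainer is a plain numpy implementation of skip-gram with negative
sampling (one hidden layer, linear projection): single-threaded and fully
deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import Alphabet, RepresentedSequence

__all__ = [
    "EmbeddingModel",
    "build_corpus",
    "train_embedding",
    "embed_sequence",
    "default_dimension",
    "save_word2vec",
    "load_word2vec",
]

logger = logging.getLogger(__name__)

#: ProtVec-style dimension for the standard alphabet, RA2Vec-style otherwise.
_DEFAULT_DIM_STANDARD = 50
_DEFAULT_DIM_REDUCED = 300


def default_dimension(alphabet: Alphabet) -> int:
    """50 for the standard 20-letter alphabet, 300 for reduced alphabets."""
    return _DEFAULT_DIM_STANDARD if alphabet.name == "no_reduction" else _DEFAULT_DIM_REDUCED


@dataclass
class EmbeddingModel:
    """A trained n-gram embedding: vocabulary of equal-length real vectors."""

    alphabet: Alphabet
    ngram_size: int
    dimension: int
    vocabulary: dict[str, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for word, vec in self.vocabulary.items():
            if vec.shape != (self.dimension,):
                raise ValueError(f"vector for {word!r} has length {vec.shape}, expected {self.dimension}")


def build_corpus(
    sequences: list[RepresentedSequence], ngram_size: int
) -> list[list[str]]:
    """Shifted non-overlapping n-gram documents for a set of sequences.

    Each sequence of length >= ngram_size yields ``ngram_size`` documents
    (shift offsets 0..ngram_size-1).  Shorter sequences contribute nothing
    (a warning is logged).
    """
    if ngram_size < 1:
        raise ValueError("ngram_size must be >= 1")
    if not sequences:
        raise ValueError("no sequences supplied")
    docs: list[list[str]] = []
    skipped = 0
    for seq in sequences:
        toks = seq.tokens
        if len(toks) < ngram_size:
            skipped += 1
            continue
        for shift in range(ngram_size):
            doc = [
                "".join(toks[i : i + ngram_size])
                for i in range(shift, len(toks) - ngram_size + 1, ngram_size)
            ]
            if doc:
                docs.append(doc)
    if skipped:
        logger.warning("%d sequence(s) shorter than ngram_size=%d skipped", skipped, ngram_size)
    return docs


def train_embedding(
    corpus: list[list[str]],
    dimension: int,
    alphabet: Alphabet,
    ngram_size: int,
    window: int = 5,
    epochs: int = 10,
    seed: int = 0,
    min_count: int = 1,
    negative: int = 5,
    learning_rate: float = 0.025,
) -> EmbeddingModel:
    """Train a skip-gram model with negative sampling on an n-gram corpus.

    The model is the classic single-hidden-layer architecture: an input
    (word) matrix and an output (context) matrix, updated by SGD on
    positive (center, context) pairs within ``window`` and ``negative``
    noise words drawn from the unigram^(3/4) distribution.  The learned
    input vectors are the embeddings.  Deterministic for fixed seed.
    """
    if not corpus:
        raise ValueError("empty corpus")
    counts: dict[str, int] = {}
    for doc in corpus:
        for w in doc:
            counts[w] = counts.get(w, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError(f"no n-gram reaches min_count={min_count}")
    w2i = {w: i for i, w in enumerate(vocab)}
    v = len(vocab)

    rng = np.random.default_rng(seed)
    w_in = (rng.random((v, dimension)) - 0.5) / dimension
    w_out = np.zeros((v, dimension))

    freq = np.array([counts[w] for w in vocab], dtype=float) ** 0.75
    noise_p = freq / freq.sum()

    encoded = [np.array([w2i[w] for w in doc if w in w2i], dtype=np.intp) for doc in corpus]
    encoded = [d for d in encoded if len(d) > 0]
    total_steps = epochs * len(encoded)
    step = 0
    for _epoch in range(epochs):
        for doc in encoded:
            lr = max(learning_rate * (1 - step / total_steps), 1e-4)
            step += 1
            for ci, center in enumerate(doc):
                lo, hi = max(0, ci - window), min(len(doc), ci + window + 1)
                for cj in range(lo, hi):
                    if cj == ci:
                        continue
                    context = doc[cj]
                    neg = rng.choice(v, size=negative, p=noise_p)
                    targets = np.concatenate(([context], neg))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    h = w_in[center]
                    scores = w_out[targets] @ h
                    preds = 1.0 / (1.0 + np.exp(-scores))
                    g = (preds - labels) * lr
                    grad_h = g @ w_out[targets]
                    w_out_update = np.outer(g, h)
                    np.add.at(w_out, targets, -w_out_update)
                    w_in[center] -= grad_h
    vocabulary = {w: w_in[w2i[w]].copy() for w in vocab}
    meta = {
        "window": window,
        "epochs": epochs,
        "seed": seed,
        "min_count": min_count,
        "negative": negative,
        "corpus": f"{len(corpus)} documents",
    }
    return EmbeddingModel(
        alphabet=alphabet,
        ngram_size=ngram_size,
        dimension=dimension,
        vocabulary=vocabulary,
        training_meta=meta,
    )


def embed_sequence(rep_seq: RepresentedSequence, model: EmbeddingModel) -> np.ndarray:
    """Sum of the vectors of all overlapping n-grams of the sequence.

    Out-of-vocabulary n-grams contribute the zero vector (count logged).
    Output length always equals ``model.dimension``.
    """
    if rep_seq.alphabet.name != model.alphabet.name:
        raise ValueError(
            f"alphabet mismatch: sequence is {rep_seq.alphabet.name!r}, "
            f"model is {model.alphabet.name!r}"
        )
    n, size = len(rep_seq), model.ngram_size
    out = np.zeros(model.dimension)
    oov = 0
    for i in range(n - size + 1):
        word = "".join(rep_seq.tokens[i : i + size])
        vec = model.vocabulary.get(word)
        if vec is None:
            oov += 1
        else:
            out += vec
    if oov:
        logger.debug("%d out-of-vocabulary n-gram(s) in %s", oov, rep_seq.source_id or "<seq>")
    return out


def save_word2vec(model: EmbeddingModel, path: str | Path) -> None:
    """Write vectors in word2vec text format ("vocab_size dim" header)."""
    with open(path, "w") as fh:
        fh.write(f"{len(model.vocabulary)} {model.dimension}\n")
        for word in sorted(model.vocabulary):
            vec = " ".join(f"{x:.8g}" for x in model.vocabulary[word])
            fh.write(f"{word} {vec}\n")


def load_word2vec(path: str | Path, alphabet: Alphabet, ngram_size: int) -> EmbeddingModel:
    """Load a word2vec text-format vector file as an :class:`EmbeddingModel`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        vocab_size, dimension = int(header[0]), int(header[1])
        vocabulary: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            vocabulary[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(vocabulary) != vocab_size:
        raise ValueError(f"{path}: header promises {vocab_size} words, found {len(vocabulary)}")
    return EmbeddingModel(
        alphabet=alphabet,
        ngram_size=ngram_size,
        dimension=dimension,
        vocabulary=vocabulary,
        training_meta={"corpus": f"loaded from {path}"},
    )
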