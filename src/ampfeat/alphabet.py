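"""Sequence representations: the standard amino-acid alphabet and reduced alphabets.

A reduced alphabet partitions the 20 standard amino acids into a smaller
number of groups sharing a physicochemical or structural property, and a
sequence is re-expressed position-wise in group labels.  Two reductions are
packaged: a 5-group hydropathy scheme (binned normalized Kyte-Doolittle
scores, labels ``H_1``..``H_5``) and a 7-group conformational-similarity
scheme (labels ``C_1``..``C_7``).  Any user-supplied partition can be loaded
from a two-column TSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "AMINO_ACIDS",
    "BUILTIN_ALPHABETS",
    "Alphabet",
    "RepresentedSequence",
    "load_alphabet",
    "reduce_sequence",
]

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Names accepted by :func:`load_alphabet` without a mapping file.
BUILTIN_ALPHABETS: tuple[str, ...] = ("no_reduction", "hydro", "conform")


@dataclass(frozen=True)
class Alphabet:
    """An ordered symbol set with a total mapping from amino acids to symbols.

    Parameters
    ----------
    name
        Identifier ("no_reduction", "hydro", "conform" or user-defined).
    symbols
        Ordered tuple of the k distinct group labels.
    mapping
        Total mapping from each of the 20 standard amino-acid letters to a
        member of ``symbols``.
    """

    name: str
    symbols: tuple[str, ...]
    mapping: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.mapping)
        if missing:
            raise ValueError(
                f"alphabet {self.name!r}: mapping not total, missing {sorted(missing)}"
            )
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"alphabet {self.name!r}: duplicate symbols")
        images = set(self.mapping[aa] for aa in AMINO_ACIDS)
        if images != set(self.symbols):
            raise ValueError(
                f"alphabet {self.name!r}: symbols {sorted(set(self.symbols) - images)} "
                "are not the image of any amino acid"
            )

    @property
    def size(self) -> int:
        """Number of symbols k."""
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        """Position of ``symbol`` in the canonical symbol order."""
        return self.symbols.index(symbol)


@dataclass(frozen=True)
class RepresentedSequence:
    """A sequence re-expressed in an alphabet's symbols (position-wise)."""

    alphabet: Alphabet
    tokens: tuple[str, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        bad = set(self.tokens) - set(self.alphabet.symbols)
        if bad:
            raise ValueError(
                f"tokens {sorted(bad)} not in alphabet {self.alphabet.name!r}"
            )

    def __len__(self) -> int:
        return len(self.tokens)


def _parse_mapping_tsv(text: str, name: str) -> Alphabet:
    mapping: dict[str, str] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{name}: line {lineno}: expected 2 columns, got {len(parts)}")
        aa, group = parts[0].upper(), parts[1]
        if aa not in AMINO_ACIDS:
            raise ValueError(f"{name}: line {lineno}: {aa!r} is not a standard amino acid")
        if aa in mapping:
            raise ValueError(f"{name}: line {lineno}: duplicate row for {aa!r}")
        mapping[aa] = group
        if group not in order:
            order.append(group)
    return Alphabet(name=name, symbols=tuple(order), mapping=mapping)


def load_alphabet(name_or_path: str | Path) -> Alphabet:
    """Load a built-in alphabet by name, or a user alphabet from a TSV file.

    Built-in names are ``"no_reduction"`` (identity, 20 symbols), ``"hydro"``
    (5 hydropathy groups) and ``"conform"`` (7 conformational-similarity
    groups).  A path must point to a two-column TSV (amino_acid, group_label;
    ``#`` comments allowed) covering all 20 amino acids.

    Raises
    ------
    ValueError
        Unknown name, non-total or ambiguous mapping file.
    """
    name = str(name_or_path)
    if name == "no_reduction":
        return Alphabet(
            name="no_reduction",
            symbols=AMINO_ACIDS,
            mapping={aa: aa for aa in AMINO_ACIDS},
        )
    if name in ("hydro", "conform"):
        text = resources.files("ampfeat").joinpath(f"tables/{name}.tsv").read_text()
        return _parse_mapping_tsv(text, name)
    path = Path(name_or_path)
    if path.is_file():
        return _parse_mapping_tsv(path.read_text(), path.stem)
    raise ValueError(
        f"unknown alphabet {name!r}: not one of {BUILTIN_ALPHABETS} and not a file"
    )


def reduce_sequence(sequence: str, alphabet: Alphabet, source_id: str = "") -> RepresentedSequence:
    """Convert an amino-acid string to its representation under ``alphabet``.

    The conversion is position-wise, so length is preserved.  Lowercase
    letters are uppercased before lookup.  Non-standard characters
    (including the padding letter 'X') raise with the offending position.
    """
    if not sequence:
        raise ValueError("cannot reduce an empty sequence")
    seq = sequence.upper()
    tokens = []
    for pos, ch in enumerate(seq):
        try:
            tokens.append(alphabet.mapping[ch])
        except KeyError:
            raise ValueError(
                f"non-standard amino acid {ch!r} at position {pos} "
                f"(sequence {source_id or sequence[:10] + '...'})"
            ) from None
    return RepresentedSequence(alphabet=alphabet, tokens=tuple(tokens), source_id=source_id)
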