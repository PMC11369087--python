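"""Peptide I/O, site-window extraction, padding filter and synthetic data.

The classification unit is a fixed-length peptide window centred on a
candidate modification site: by default 15 residues upstream and
downstream of the site, i.e. a 31-mer with the site at position 16
(1-based).  Windows that would run past a protein terminus are rejected
rather than padded, so downstream feature extraction never sees the 'X'
placeholder letter; records containing 'X' (padded upstream data) can be
dropped with :func:`filter_padded`.

The synthetic generator emulates the shape of a curated AMPylation-site
dataset: fixed-length 31-mers with a binary label, positives centred on
T/Y (the primarily modified residues) and optionally carrying a
class-dependent residue-composition tilt and/or a planted motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS

__all__ = [
    "PeptideRecord",
    "read_peptides",
    "write_peptides",
    "extract_window",
    "filter_padded",
    "generate_synthetic",
    "BACKGROUND_FREQUENCIES",
]

logger = logging.getLogger(__name__)

#: Approximate background amino-acid frequencies in the UniProt/Swiss-Prot
#: proteome, normalized over the 20 standard residues.
BACKGROUND_FREQUENCIES: dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0473,
    "S": 0.0665, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


@dataclass(frozen=True)
class PeptideRecord:
    """A site-centred peptide with a binary modification label."""

    id: str
    sequence: str
    label: int | None = None

    @property
    def center_residue(self) -> str:
        """The site residue: the middle position of an odd-length window."""
        return self.sequence[len(self.sequence) // 2]


def read_peptides(path: str | Path, format: str | None = None) -> list[PeptideRecord]:
    """Read peptides from FASTA or CSV.

    FASTA description lines may carry a ``label=0|1`` token; CSV needs
    columns ``id``, ``sequence`` and optionally ``label``.  Sequences are
    uppercased on load.  Format is inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() in (".csv", ".tsv") else "fasta"
    records: list[PeptideRecord] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            label = None
            for token in rec.description.split():
                if token.startswith("label="):
                    label = int(token.split("=", 1)[1])
            records.append(PeptideRecord(id=rec.id, sequence=str(rec.seq).upper(), label=label))
    elif format == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep)
        missing = {"id", "sequence"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        for _, row in df.iterrows():
            label = int(row["label"]) if "label" in df.columns and pd.notna(row["label"]) else None
            records.append(
                PeptideRecord(id=str(row["id"]), sequence=str(row["sequence"]).upper(), label=label)
            )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'csv')")
    return records


def write_peptides(records: list[PeptideRecord], path: str | Path, format: str | None = None) -> None:
    """Write peptides as FASTA (``label=`` token in the description) or CSV."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() in (".csv", ".tsv") else "fasta"
    if format == "fasta":
        seq_records = [
            SeqRecord(
                Seq(r.sequence),
                id=r.id,
                description="" if r.label is None else f"label={r.label}",
            )
            for r in records
        ]
        SeqIO.write(seq_records, str(path), "fasta")
    elif format == "csv":
        df = pd.DataFrame(
            {
                "id": [r.id for r in records],
                "sequence": [r.sequence for r in records],
                "label": [r.label for r in records],
            }
        )
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def extract_window(
    protein: str,
    site_pos: int,
    flank: int = 15,
    label: int | None = None,
    record_id: str | None = None,
) -> PeptideRecord:
    """Extract the (2*flank+1)-mer centred on a 1-based site position.

    Sites closer than ``flank`` to either terminus are rejected with an
    explicit reason (no padding is performed).
    """
    n = len(protein)
    if not 1 <= site_pos <= n:
        raise ValueError(f"site position {site_pos} outside protein of length {n}")
    if site_pos - flank < 1 or site_pos + flank > n:
        raise ValueError(
            f"site {site_pos} is closer than {flank} residues to a terminus "
            f"of the length-{n} protein; window rejected"
        )
    window = protein[site_pos - flank - 1 : site_pos + flank].upper()
    return PeptideRecord(
        id=record_id or f"site_{site_pos}", sequence=window, label=label
    )


def filter_padded(records: list[PeptideRecord]) -> tuple[list[PeptideRecord], int]:
    """Drop records whose sequence contains the padding letter 'X'.

    Returns the kept records (unchanged) and the number dropped.
    """
    kept = [r for r in records if "X" not in r.sequence.upper()]
    dropped = len(records) - len(kept)
    if dropped == len(records) and records:
        logger.warning("all %d records contained 'X'; nothing kept", dropped)
    return kept, dropped


def _tilted(freqs: np.ndarray, shift: dict[str, float] | None) -> np.ndarray:
    if not shift:
        return freqs
    out = freqs.copy()
    for aa, logodds in shift.items():
        if aa not in AMINO_ACIDS:
            raise ValueError(f"composition_shift names unknown residue {aa!r}")
        out[AMINO_ACIDS.index(aa)] *= np.exp(logodds)
    return out / out.sum()


def generate_synthetic(
    n_pos: int = 153,
    n_neg: int = 250,
    length: int = 31,
    composition_shift: dict[str, float] | None = None,
    motif: str | None = None,
    center_residues: tuple[str, ...] | None = ("T", "Y"),
    seed: int = 0,
) -> list[PeptideRecord]:
    """Generate a labelled synthetic peptide dataset.

    Negatives are i.i.d. draws from background amino-acid frequencies.
    Positives may differ in three independently switchable ways: the
    centre residue is drawn from ``center_residues`` (default T/Y, the
    primarily modified residues; pass None to disable), their residue
    distribution is tilted by ``composition_shift`` (per-residue log-odds
    added to the background log-frequencies), and an optional ``motif``
    string is planted immediately downstream of the centre.  Deterministic
    for a fixed seed.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be non-negative")
    if motif is not None and len(motif) > length // 2:
        raise ValueError(f"motif {motif!r} does not fit downstream of the centre")
    rng = np.random.default_rng(seed)
    aa = np.array(AMINO_ACIDS)
    bg = np.array([BACKGROUND_FREQUENCIES[a] for a in AMINO_ACIDS])
    bg = bg / bg.sum()
    pos_freqs = _tilted(bg, composition_shift)
    center = length // 2  # 0-based centre of an odd-length window

    records: list[PeptideRecord] = []
    for i in range(n_pos):
        chars = rng.choice(aa, size=length, p=pos_freqs)
        if center_residues:
            chars[center] = center_residues[rng.integers(len(center_residues))]
        if motif:
            chars[center + 1 : center + 1 + len(motif)] = list(motif)
        records.append(PeptideRecord(id=f"pos_{i}", sequence="".join(chars), label=1))
    for i in range(n_neg):
        chars = rng.choice(aa, size=length, p=bg)
        records.append(PeptideRecord(id=f"neg_{i}", sequence="".join(chars), label=0))
    return records
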