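"""Protein sequence and pair-label I/O, and integer tokenization.

Sequences are read from FASTA, pair labels from 3-column TSV
(``id_a<TAB>id_b<TAB>label``). Each amino acid is mapped to a fixed
integer code (1..20) and sequences are zero-padded to a fixed length so
they can be fed to the convolutional encoder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Fixed integer code for each of the 20 standard amino acids.
#: Position 0 is reserved for padding.
AA_CODES: dict[str, int] = {
    "A": 1, "G": 2, "V": 3, "I": 4, "L": 5, "F": 6, "P": 7, "Y": 8,
    "M": 9, "T": 10, "S": 11, "H": 12, "N": 13, "Q": 14, "W": 15,
    "R": 16, "K": 17, "D": 18, "E": 19, "C": 20,
}

#: Inverse map, used for round-trip decoding in tests and diagnostics.
CODE_TO_AA: dict[int, str] = {v: k for k, v in AA_CODES.items()}

DEFAULT_PADDED_LENGTH = 5000


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class TokenSequence:
    """Fixed-length integer encoding of a protein.

    ``tokens`` holds codes in [1, 20] for residues and 0 at padding
    positions; its length always equals ``padded_length``.
    """

    tokens: np.ndarray
    padded_length: int

    def __post_init__(self) -> None:
        if len(self.tokens) != self.padded_length:
            raise ValueError(
                f"token vector has length {len(self.tokens)}, "
                f"expected padded_length={self.padded_length}"
            )

    def decode(self) -> str:
        """Recover the (possibly truncated) residue string, ignoring padding."""
        return "".join(CODE_TO_AA[t] for t in self.tokens if t != 0)


@dataclass(frozen=True)
class LabeledPair:
    """A labeled protein pair: label 1 = interacting, 0 = non-interacting."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) FASTA file into ProteinRecords.

    The header token before the first whitespace is used as the id.
    Raises ``ValueError`` on duplicate ids or records with empty sequences.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate id in FASTA: {rid!r}")
        seen.add(rid)
        records.append(ProteinRecord(id=rid, sequence=str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def tokenize(
    record: ProteinRecord,
    L: int = DEFAULT_PADDED_LENGTH,
    pad_side: str = "trailing",
    strict: bool = False,
) -> TokenSequence:
    """Map a protein to its fixed-length integer token sequence.

    Residues are encoded by the fixed 20-letter map; the result is padded
    with 0 to length ``L`` on ``pad_side`` ("trailing" or "leading").
    Sequences longer than ``L`` are truncated to their first ``L`` residues
    with a warning. Non-standard residues (B, J, O, U, X, Z, ...) map to the
    padding token 0 with a warning, or raise if ``strict`` is True.
    """
    if L < 1:
        raise ValueError("padded length L must be >= 1")
    if pad_side not in ("trailing", "leading"):
        raise ValueError(f"pad_side must be 'trailing' or 'leading', got {pad_side!r}")

    seq = record.sequence
    if len(seq) > L:
        warnings.warn(
            f"protein {record.id!r}: sequence length {len(seq)} exceeds L={L}; "
            "keeping the first L residues",
            stacklevel=2,
        )
        seq = seq[:L]

    codes = np.zeros(len(seq), dtype=np.int64)
    for i, aa in enumerate(seq):
        code = AA_CODES.get(aa)
        if code is None:
            if strict:
                raise ValueError(
                    f"protein {record.id!r}: non-standard residue {aa!r} at position {i}"
                )
            logger.warning(
                "protein %r: non-standard residue %r at position %d mapped to 0",
                record.id, aa, i,
            )
            code = 0
        codes[i] = code

    tokens = np.zeros(L, dtype=np.int64)
    if pad_side == "trailing":
        tokens[: len(codes)] = codes
    else:
        tokens[L - len(codes):] = codes
    return TokenSequence(tokens=tokens, padded_length=L)


def read_pairs(path: str | Path) -> list[LabeledPair]:
    """Read labeled pairs from headerless 3-column TSV (id_a, id_b, label)."""
    pairs: list[LabeledPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            id_a, id_b, raw_label = fields
            try:
                label = int(raw_label)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer label {raw_label!r}") from exc
            if label not in (0, 1):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label}")
            pairs.append(LabeledPair(id_a=id_a, id_b=id_b, label=label))
    return pairs


def write_pairs(pairs: Iterable[LabeledPair], path: str | Path) -> None:
    """Write labeled pairs as headerless 3-column TSV."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.label}\n")
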