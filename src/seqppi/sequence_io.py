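"""Reading, validating and writing protein sequences and pair-label tables.

Inputs are standard FASTA (via Biopython) plus a three-column TSV of
protein pairs (``id_a``, ``id_b``, ``label``).  Sequence pairs in which
either partner is shorter than 50 residues are dropped by default, since
such entries are likely fragments rather than full proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .matrices import AMBIGUITY_CODES, AMINO_ACIDS

logger = logging.getLogger(__name__)

#: Minimum sequence length retained by default; shorter entries are
#: treated as fragments.
MIN_SEQUENCE_LENGTH = 50

_VALID_LETTERS = frozenset(AMINO_ACIDS) | AMBIGUITY_CODES

_TRUE_LABELS = {"1", "yes", "true", "interacting"}
_FALSE_LABELS = {"0", "no", "false", "non-interacting", "noninteracting"}


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence.

    ``residues`` is upper-case; the 20 standard letters plus the common
    ambiguity codes (B, Z, J, X, U, O, ``*``) are accepted.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        residues = self.residues.upper()
        bad = sorted(set(residues) - _VALID_LETTERS)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {''.join(bad)!r}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairRecord:
    """A labelled protein pair: label 1 = interacting, 0 = non-interacting.

    ``label`` may be None for prediction-only pairs.
    """

    id_a: str
    id_b: str
    label: int | None

    def __post_init__(self) -> None:
        if self.label not in (0, 1, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def pair_id(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


def read_fasta(path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of validated :class:`ProteinSequence`.

    Raises ``ValueError`` for an empty file or duplicate record ids.
    Lower-case residues are upper-cased; multi-line records are joined.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    sequences: list[ProteinSequence] = []
    for rec in records:
        if not rec.id:
            raise ValueError(f"{path}: record with empty id")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        sequences.append(ProteinSequence(rec.id, str(rec.seq)))
    return sequences


def write_fasta(path, sequences: Iterable[ProteinSequence], width: int = 60) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def _coerce_label(raw: str, line_no: int, path, allow_unlabeled: bool) -> int | None:
    token = raw.strip().lower()
    if token in _TRUE_LABELS:
        return 1
    if token in _FALSE_LABELS:
        return 0
    if allow_unlabeled and token in ("", "?", "na"):
        return None
    raise ValueError(f"{path}:{line_no}: unrecognised label {raw!r}")


def read_pairs(
    path, sequences: Sequence[ProteinSequence], allow_unlabeled: bool = False
) -> list[PairRecord]:
    """Read a pair-label TSV and check every id against ``sequences``.

    The file has a header line ``id_a<TAB>id_b<TAB>label``.  Labels
    ``1/0``, ``yes/no`` and ``true/false`` are accepted case-insensitively.
    Self-pairs and duplicates are retained with a logged warning.
    """
    path = Path(path)
    known = {s.id for s in sequences}
    pairs: list[PairRecord] = []
    seen_pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty pair table")
        cols = header.rstrip("\n").split("\t")
        if [c.strip().lower() for c in cols[:3]] != ["id_a", "id_b", "label"]:
            raise ValueError(
                f"{path}:1: expected header 'id_a\\tid_b\\tlabel', got {header.strip()!r}"
            )
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected 3 tab-separated columns")
            id_a, id_b, raw_label = fields[0].strip(), fields[1].strip(), fields[2]
            for pid in (id_a, id_b):
                if pid not in known:
                    raise ValueError(f"{path}:{line_no}: unknown protein id {pid!r}")
            if id_a == id_b:
                logger.warning("%s:%d: self-pair (%s, %s) retained", path, line_no, id_a, id_b)
            key = (id_a, id_b)
            if key in seen_pairs:
                logger.warning("%s:%d: duplicate pair (%s, %s) retained", path, line_no, id_a, id_b)
            seen_pairs.add(key)
            label = _coerce_label(raw_label, line_no, path, allow_unlabeled)
            pairs.append(PairRecord(id_a, id_b, label))
    if not pairs:
        raise ValueError(f"{path}: pair table has a header but no rows")
    return pairs


def write_pairs(path, pairs: Iterable[PairRecord]) -> None:
    """Write pairs in the TSV layout :func:`read_pairs` accepts."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tlabel\n")
        for p in pairs:
            label = "?" if p.label is None else str(p.label)
            fh.write(f"{p.id_a}\t{p.id_b}\t{label}\n")


def filter_short(
    pairs: Sequence[PairRecord],
    sequences: Sequence[ProteinSequence],
    min_len: int = MIN_SEQUENCE_LENGTH,
) -> list[PairRecord]:
    """Drop pairs in which either protein is shorter than ``min_len``.

    The boundary is inclusive: a protein of exactly ``min_len`` residues
    is retained.  The number of removed pairs is logged.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    lengths = {s.id: len(s) for s in sequences}
    kept = [
        p for p in pairs if lengths[p.id_a] >= min_len and lengths[p.id_b] >= min_len
    ]
    removed = len(pairs) - len(kept)
    if removed:
        logger.info(
            "length filter (min %d aa): removed %d of %d pairs", min_len, removed, len(pairs)
        )
    return kept
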