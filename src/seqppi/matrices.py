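"""Amino-acid substitution matrices.

The default encoding matrix is BLOSUM62 in half-bit integer units, the
matrix protein BLAST uses by default.  Rows and columns follow the fixed
alphabet ``ARNDCQEGHILKMFPSTWYV``; alternative matrices can be read from
NCBI-format text files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# Letters that may appear in real FASTA records but carry no single
# unambiguous substitution row: B (Asx), Z (Glx), J (Xle), X (unknown),
# U (Sec), O (Pyl) and the stop marker.
AMBIGUITY_CODES = frozenset("BZJXUO*")

_BLOSUM62_ROWS = (
    (4, -1, -2, -2, 0, -1, -1, 0, -2, -1, -1, -1, -1, -2, -1, 1, 0, -3, -2, 0),  # A
    (-1, 5, 0, -2, -3, 1, 0, -2, 0, -3, -2, 2, -1, -3, -2, -1, -1, -3, -2, -3),  # R
    (-2, 0, 6, 1, -3, 0, 0, 0, 1, -3, -3, 0, -2, -3, -2, 1, 0, -4, -2, -3),  # N
    (-2, -2, 1, 6, -3, 0, 2, -1, -1, -3, -4, -1, -3, -3, -1, 0, -1, -4, -3, -3),  # D
    (0, -3, -3, -3, 9, -3, -4, -3, -3, -1, -1, -3, -1, -2, -3, -1, -1, -2, -2, -1),  # C
    (-1, 1, 0, 0, -3, 5, 2, -2, 0, -3, -2, 1, 0, -3, -1, 0, -1, -2, -1, -2),  # Q
    (-1, 0, 0, 2, -4, 2, 5, -2, 0, -3, -3, 1, -2, -3, -1, 0, -1, -3, -2, -2),  # E
    (0, -2, 0, -1, -3, -2, -2, 6, -2, -4, -4, -2, -3, -3, -2, 0, -2, -2, -3, -3),  # G
    (-2, 0, 1, -1, -3, 0, 0, -2, 8, -3, -3, -1, -2, -1, -2, -1, -2, -2, 2, -3),  # H
    (-1, -3, -3, -3, -1, -3, -3, -4, -3, 4, 2, -3, 1, 0, -3, -2, -1, -3, -1, 3),  # I
    (-1, -2, -3, -4, -1, -2, -3, -4, -3, 2, 4, -2, 2, 0, -3, -2, -1, -2, -1, 1),  # L
    (-1, 2, 0, -1, -3, 1, 1, -2, -1, -3, -2, 5, -1, -3, -1, 0, -1, -3, -2, -2),  # K
    (-1, -1, -2, -3, -1, 0, -2, -3, -2, 1, 2, -1, 5, 0, -2, -1, -1, -1, -1, 1),  # M
    (-2, -3, -3, -3, -2, -3, -3, -3, -1, 0, 0, -3, 0, 6, -4, -2, -2, 1, 3, -1),  # F
    (-1, -2, -2, -1, -3, -1, -1, -2, -2, -3, -3, -1, -2, -4, 7, -1, -1, -4, -3, -2),  # P
    (1, -1, 1, 0, -1, 0, 0, 0, -1, -2, -2, 0, -1, -2, -1, 4, 1, -3, -2, -2),  # S
    (0, -1, 0, -1, -1, -1, -1, -2, -2, -1, -1, -1, -1, -2, -1, 1, 5, -2, -2, 0),  # T
    (-3, -3, -4, -4, -2, -2, -3, -2, -2, -3, -2, -3, -1, 1, -4, -3, -2, 11, 2, -3),  # W
    (-2, -2, -2, -3, -2, -1, -2, -3, 2, -1, -1, -2, -1, 3, -3, -2, -2, 2, 7, -1),  # Y
    (0, -3, -3, -3, -1, -2, -2, -3, -3, 3, 1, -2, 1, -1, -2, -2, 0, -3, -1, 4),  # V
)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 amino-acid substitution score table.

    Parameters
    ----------
    scores
        20x20 array of substitution scores; ``scores[i, j]`` scores the
        substitution of ``alphabet[i]`` by ``alphabet[j]``.
    alphabet
        Ordered string of the 20 residue letters fixing row/column meaning.
    name
        Human-readable identifier carried into model archives.
    """

    scores: np.ndarray
    alphabet: str = AMINO_ACIDS
    name: str = "custom"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (20, 20):
            raise ValueError(f"expected a 20x20 score table, got {scores.shape}")
        if len(self.alphabet) != 20 or len(set(self.alphabet)) != 20:
            raise ValueError("alphabet must contain 20 distinct letters")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.alphabet)})

    def row(self, residue: str) -> np.ndarray:
        """Score row for ``residue``; ambiguity codes map to the zero row."""
        idx = self._index.get(residue)
        if idx is None:
            return np.zeros(20)
        return self.scores[idx]

    def __contains__(self, residue: str) -> bool:
        return residue in self._index


def blosum62() -> SubstitutionMatrix:
    """The canonical NCBI BLOSUM62 table (half-bit integer scores)."""
    return SubstitutionMatrix(np.array(_BLOSUM62_ROWS, dtype=float), AMINO_ACIDS, "BLOSUM62")


def read_ncbi_matrix(path) -> SubstitutionMatrix:
    """Read a substitution matrix in NCBI text format.

    The format is the one ``blastp`` and EMBOSS ship: ``#`` comment lines,
    a header row of column letters, then one row per letter.  Columns
    beyond the 20 standard amino acids (B, Z, X, ``*``) are dropped.
    """
    from Bio.Align import substitution_matrices

    with open(path) as handle:
        raw = substitution_matrices.read(handle)
    missing = [a for a in AMINO_ACIDS if a not in raw.alphabet]
    if missing:
        raise ValueError(f"matrix file {path} lacks rows for residues {''.join(missing)}")
    scores = np.array([[raw[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float)
    return SubstitutionMatrix(scores, AMINO_ACIDS, name=str(path))
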