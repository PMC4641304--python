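"""Fixed-length pair features from variable-length protein sequences.

A length-N protein is first expanded into its substitution matrix
representation (SMR): an N x 20 real matrix whose i-th row is the
BLOSUM62 score row of residue i.  The SMR is compressed with the
orthonormal 2-D type-II discrete cosine transform (DCT); because the DCT
concentrates signal energy in the low-frequency corner, keeping the
top-left 20 x 20 coefficient block (400 values, row-major) yields a
fixed-length descriptor for any sequence length.  A protein pair is the
concatenation of its two descriptors: an 800-dimensional vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.fft

from .matrices import SubstitutionMatrix, blosum62
from .sequence_io import PairRecord, ProteinSequence

logger = logging.getLogger(__name__)

#: Default number of retained DCT coefficients per protein.
N_COEFFICIENTS = 400


@dataclass(frozen=True)
class SMRMatrix:
    """Substitution matrix representation of one protein (N x 20)."""

    values: np.ndarray
    source_id: str


@dataclass(frozen=True)
class DCTDescriptor:
    """Fixed-length low-frequency DCT descriptor of one protein."""

    coefficients: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coefficients, dtype=float)
        if coeff.ndim != 1:
            raise ValueError("descriptor must be a flat vector")
        if not np.all(np.isfinite(coeff)):
            raise ValueError(f"descriptor for {self.source_id!r} has non-finite entries")
        object.__setattr__(self, "coefficients", coeff)

    def __len__(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class PairFeature:
    """Concatenated descriptor pair with an optional binary label."""

    vector: np.ndarray
    pair_id: tuple[str, str]
    label: int | None = None

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if vec.ndim != 1:
            raise ValueError("pair feature must be a flat vector")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")
        object.__setattr__(self, "vector", vec)


def build_smr(seq: ProteinSequence, matrix: SubstitutionMatrix | None = None) -> SMRMatrix:
    """Expand a sequence into its N x 20 substitution matrix representation.

    Row i is the substitution-score row of residue i.  Ambiguity codes
    have no score row and map to an all-zero row (no evolutionary
    signal); each such residue is counted and logged once per sequence.
    """
    matrix = matrix if matrix is not None else blosum62()
    rows = np.empty((len(seq), 20))
    n_ambiguous = 0
    for i, residue in enumerate(seq.residues):
        if residue in matrix:
            rows[i] = matrix.row(residue)
        else:
            rows[i] = 0.0
            n_ambiguous += 1
    if n_ambiguous:
        logger.warning(
            "sequence %s: %d ambiguous residue(s) mapped to the zero row",
            seq.id,
            n_ambiguous,
        )
    return SMRMatrix(rows, seq.id)


def dct2(signal: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D type-II DCT; output shape equals input shape.

    Orthonormality means the transform preserves the squared Frobenius
    norm (Parseval), so coefficient magnitudes are comparable across
    sequence lengths.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("dct2 requires a non-empty matrix")
    if not np.all(np.isfinite(signal)):
        raise ValueError("dct2 requires finite input")
    return scipy.fft.dctn(signal, type=2, norm="ortho")


def select_coefficients(dct_matrix: np.ndarray, n_coefficients: int = N_COEFFICIENTS,
                        source_id: str = "") -> DCTDescriptor:
    """Keep the low-frequency top-left block of a DCT matrix, flattened.

    With 20 columns and ``n_coefficients`` = 400 this is the top-left
    20 x 20 block in row-major order.  Matrices with fewer rows than the
    block are zero-padded, so the descriptor length is always exactly
    ``n_coefficients``.
    """
    dct_matrix = np.asarray(dct_matrix, dtype=float)
    if n_coefficients <= 0:
        raise ValueError("n_coefficients must be positive")
    n_cols = dct_matrix.shape[1]
    if n_coefficients % n_cols:
        raise ValueError(
            f"n_coefficients ({n_coefficients}) must be a multiple of the "
            f"column count ({n_cols})"
        )
    n_rows = n_coefficients // n_cols
    block = dct_matrix[:n_rows]
    if block.shape[0] < n_rows:
        block = np.vstack([block, np.zeros((n_rows - block.shape[0], n_cols))])
    return DCTDescriptor(block.reshape(-1).copy(), source_id)


def protein_descriptor(
    seq: ProteinSequence,
    matrix: SubstitutionMatrix | None = None,
    n_coefficients: int = N_COEFFICIENTS,
) -> DCTDescriptor:
    """SMR -> 2-D DCT -> low-frequency block, for one protein."""
    smr = build_smr(seq, matrix)
    return select_coefficients(dct2(smr.values), n_coefficients, seq.id)


def pair_feature(desc_a: DCTDescriptor, desc_b: DCTDescriptor,
                 label: int | None = None) -> PairFeature:
    """Concatenate two descriptors (in pair order) into one feature vector."""
    if len(desc_a) != len(desc_b):
        raise ValueError(
            f"descriptor length mismatch: {desc_a.source_id!r} has {len(desc_a)}, "
            f"{desc_b.source_id!r} has {len(desc_b)}"
        )
    vector = np.concatenate([desc_a.coefficients, desc_b.coefficients])
    return PairFeature(vector, (desc_a.source_id, desc_b.source_id), label)


def pair_features(
    pairs: Sequence[PairRecord],
    sequences: Sequence[ProteinSequence] | Mapping[str, ProteinSequence],
    matrix: SubstitutionMatrix | None = None,
    n_coefficients: int = N_COEFFICIENTS,
    swap_augment: bool = False,
) -> list[PairFeature]:
    """Descriptors for every protein, then one feature per pair.

    Each distinct protein is transformed once and reused across pairs.
    With ``swap_augment`` every labelled pair additionally contributes
    the reversed-order feature, making downstream training order-free.
    """
    if not isinstance(sequences, Mapping):
        sequences = {s.id: s for s in sequences}
    matrix = matrix if matrix is not None else blosum62()
    needed = {pid for p in pairs for pid in (p.id_a, p.id_b)}
    descriptors = {
        pid: protein_descriptor(sequences[pid], matrix, n_coefficients) for pid in sorted(needed)
    }
    out: list[PairFeature] = []
    for p in pairs:
        out.append(pair_feature(descriptors[p.id_a], descriptors[p.id_b], p.label))
        if swap_augment:
            out.append(pair_feature(descriptors[p.id_b], descriptors[p.id_a], p.label))
    return out


def write_feature_table(path, features: Sequence[PairFeature]) -> None:
    """Write pair features as TSV: id_a, id_b, label, f0000..fNNNN.

    Floats are written with ``repr`` (shortest round-trip) precision, so
    a written table reads back bit-identically.
    """
    if not features:
        raise ValueError("no features to write")
    width = features[0].vector.size
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tlabel\t" + "\t".join(f"f{i:04d}" for i in range(width)) + "\n")
        for f in features:
            if f.vector.size != width:
                raise ValueError("inconsistent feature lengths")
            label = "" if f.label is None else str(f.label)
            values = "\t".join(repr(float(v)) for v in f.vector)
            fh.write(f"{f.pair_id[0]}\t{f.pair_id[1]}\t{label}\t{values}\n")


def read_feature_table(path) -> list[PairFeature]:
    """Read a TSV written by :func:`write_feature_table`."""
    import pandas as pd

    frame = pd.read_csv(
        path, sep="\t", dtype={"id_a": str, "id_b": str}, float_precision="round_trip"
    )
    required = {"id_a", "id_b", "label"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)} plus feature columns")
    value_cols = [c for c in frame.columns if c.startswith("f")]
    out = []
    for _, row in frame.iterrows():
        label = None if pd.isna(row["label"]) else int(row["label"])
        vec = row[value_cols].to_numpy(dtype=float)
        out.append(PairFeature(vec, (row["id_a"], row["id_b"]), label))
    return out
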