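"""Protein scoring schemes for local alignment.

The default scheme is BLOSUM62 with affine gap penalties 11/1 and the
published Karlin-Altschul parameters for that combination (lambda = 0.267
nats per raw-score unit, K = 0.041), which back the bit-score and E-value
statistics used throughout the search stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: Canonical residue order used for all encoded sequences and profiles.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: BLOSUM62 background frequencies (Henikoff & Henikoff), indexed as AMINO_ACIDS.
BACKGROUND = np.array(
    [
        0.074,  # A
        0.025,  # C
        0.054,  # D
        0.054,  # E
        0.047,  # F
        0.074,  # G
        0.026,  # H
        0.068,  # I
        0.058,  # K
        0.099,  # L
        0.025,  # M
        0.045,  # N
        0.039,  # P
        0.034,  # Q
        0.052,  # R
        0.057,  # S
        0.051,  # T
        0.073,  # V
        0.013,  # W
        0.032,  # Y
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Index 20 is the catch-all for ambiguity codes (B, Z, X, U, O, ...); it is
# scored as the worst (minimum) entry of the relevant matrix column.
AMBIGUOUS_INDEX = 20


def _blosum62_extended() -> np.ndarray:
    raw = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = int(raw[a, b])
    core = mat[:20, :20]
    mat[AMBIGUOUS_INDEX, :20] = core.min(axis=0)
    mat[:20, AMBIGUOUS_INDEX] = core.min(axis=1)
    mat[AMBIGUOUS_INDEX, AMBIGUOUS_INDEX] = core.min()
    return mat


BLOSUM62 = _blosum62_extended()


def encode(seq: str) -> np.ndarray:
    """Encode a protein sequence as integer indices into AMINO_ACIDS.

    Ambiguity codes map to the worst-case index so they can never create
    spurious high-scoring matches.
    """
    if not seq:
        raise ValueError("empty sequence")
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _AA_INDEX.get(ch, AMBIGUOUS_INDEX)
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and score statistics.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST convention).
    ``lambda_`` and ``K`` are the Karlin-Altschul parameters used to convert
    raw scores into bit scores and E-values.
    """

    substitution_matrix: np.ndarray = field(default_factory=lambda: BLOSUM62)
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    K: float = 0.041

    def __post_init__(self):
        m = np.asarray(self.substitution_matrix)
        if m.shape not in ((20, 20), (21, 21)):
            raise ValueError("substitution matrix must be 20x20 or 21x21")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda_ and K must be positive")
        core = m[:20, :20]
        if float(BACKGROUND @ core @ BACKGROUND) >= 0:
            raise ValueError("expected score under background must be negative")
        if m.shape == (20, 20):
            ext = np.zeros((21, 21), dtype=np.int32)
            ext[:20, :20] = core
            ext[AMBIGUOUS_INDEX, :20] = core.min(axis=0)
            ext[:20, AMBIGUOUS_INDEX] = core.min(axis=1)
            ext[AMBIGUOUS_INDEX, AMBIGUOUS_INDEX] = core.min()
            object.__setattr__(self, "substitution_matrix", ext)
        else:
            object.__setattr__(self, "substitution_matrix", m.astype(np.int32))


DEFAULT_SCHEME = ScoringScheme()
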