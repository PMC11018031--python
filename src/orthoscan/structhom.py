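"""Structure-based ortholog screening.

Kabsch least-squares superposition of C-alpha traces, confidence-trace
domain segmentation of predicted models, the cross-model RMSD < 5 A
consensus rule, the RMSD < 3 A ortholog-acceptance rule, and the domain
topology / minimum length filters.

Structures are consumed as PDB-format C-alpha coordinate files with a
per-residue confidence value (pLDDT convention) in the B-factor column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass
class StructureModel:
    """C-alpha trace of one predicted model with per-residue confidence."""

    model_id: str
    coords: np.ndarray  # (n, 3)
    confidence: np.ndarray  # (n,), 0-100
    sequence: str

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        n = len(self.sequence)
        if self.coords.shape != (n, 3):
            raise ValueError("residue count must equal sequence length")
        if self.confidence.shape != (n,):
            raise ValueError("one confidence value per residue required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.confidence < 0) or np.any(self.confidence > 100):
            raise ValueError("confidence must be within [0, 100]")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, model_id: str | None = None) -> "StructureModel":
        """1-based inclusive residue slice."""
        if not 1 <= start <= end <= len(self):
            raise ValueError("slice out of bounds")
        return StructureModel(
            model_id=model_id or f"{self.model_id}[{start}-{end}]",
            coords=self.coords[start - 1 : end],
            confidence=self.confidence[start - 1 : end],
            sequence=self.sequence[start - 1 : end],
        )


@dataclass(frozen=True)
class DomainInterval:
    """A contiguous high-confidence region of one model (1-based inclusive)."""

    model_id: str
    start: int
    end: int
    mean_confidence: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_structure(path: str | Path, model_id: str | None = None) -> StructureModel:
    """Read a C-alpha PDB file; the B-factor column is the confidence."""
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, extra_fields=["b_factor"])
    if np.any(arr.ins_code != ""):
        raise ValueError("insertion codes are not supported")
    ca = arr[arr.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"no C-alpha atoms in {path}")
    seq = "".join(
        ProteinSequence.convert_letter_3to1(rn.capitalize()) for rn in ca.res_name
    )
    return StructureModel(
        model_id=model_id or Path(path).stem,
        coords=ca.coord.astype(float),
        confidence=ca.b_factor.astype(float),
        sequence=seq,
    )


def write_structure(model: StructureModel, path: str | Path) -> None:
    n = len(model)
    arr = struc.AtomArray(n)
    arr.coord = model.coords
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(
        [ProteinSequence.convert_letter_1to3(c).upper() for c in model.sequence]
    )
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.full(n, False)
    arr.set_annotation("b_factor", model.confidence.astype(float))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def kabsch_superpose(
    A: np.ndarray,
    B: np.ndarray,
    correspondence: Sequence[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of B onto A.

    Returns (R, t, rmsd) minimising ||R b + t - a|| over the corresponded
    atom pairs (0-based indices; identity correspondence if omitted). The
    SVD determinant correction excludes reflections.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if correspondence is None:
        if A.shape != B.shape:
            raise ValueError("coordinate sets differ in length; give a correspondence")
        a, b = A, B
    else:
        idx = np.asarray(list(correspondence), dtype=int)
        a = A[idx[:, 0]]
        b = B[idx[:, 1]]
    if len(a) < 3:
        raise ValueError("at least 3 corresponded pairs required")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    ac = a - ca
    bc = b - cb
    if np.linalg.matrix_rank(ac, tol=1e-8) < 2 or np.linalg.matrix_rank(bc, tol=1e-8) < 2:
        raise ValueError("corresponded atoms are collinear")
    H = bc.T @ ac
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = bc @ R.T - ac
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return R, t, rmsd


def segment_domains(
    model: StructureModel,
    min_confidence: float = 70.0,
    window: int = 15,
    min_len: int = 40,
    merge_gap: int = 10,
) -> list[DomainInterval]:
    """Confidence-trace segmentation into candidate globular domains.

    The confidence profile is smoothed with a centered moving average
    (truncated at the chain ends); maximal runs of smoothed confidence >=
    min_confidence are taken, each boundary is then extended outwards while
    the raw confidence still passes the threshold, runs separated by fewer
    than merge_gap residues are merged, and runs shorter than min_len are
    dropped.
    """
    conf = model.confidence
    n = len(conf)
    half = window // 2
    smoothed = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        smoothed[i] = conf[lo:hi].mean()
    above = smoothed >= min_confidence
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # snap boundaries to the raw trace
    for run in runs:
        while run[0] > 0 and conf[run[0] - 1] >= min_confidence:
            run[0] -= 1
        while run[1] < n - 1 and conf[run[1] + 1] >= min_confidence:
            run[1] += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], run[1])
        else:
            merged.append(run)
    out = []
    for lo, hi in merged:
        if hi - lo + 1 >= min_len:
            out.append(
                DomainInterval(
                    model_id=model.model_id,
                    start=lo + 1,
                    end=hi + 1,
                    mean_confidence=float(conf[lo : hi + 1].mean()),
                )
            )
    return out


def cross_model_consensus(
    models: Sequence[StructureModel], consensus_rmsd_max: float = 5.0
) -> tuple[bool, StructureModel | None, np.ndarray]:
    """Do independent models of the same region agree on one fold?

    All pairwise Kabsch RMSDs over the shared region (identity
    correspondence) are computed; consensus holds iff the maximum pairwise
    RMSD is strictly below consensus_rmsd_max, in which case the model with
    the lowest mean RMSD to the others (ties: lowest model_id) is the
    representative.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    n = len(models[0])
    if any(len(m) != n for m in models):
        raise ValueError("models must cover the same sequence region")
    k = len(models)
    rmsds = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            _, _, r = kabsch_superpose(models[i].coords, models[j].coords)
            rmsds[i, j] = rmsds[j, i] = r
    if rmsds.max() >= consensus_rmsd_max:
        return False, None, rmsds
    mean_r = rmsds.sum(axis=1) / (k - 1)
    order = sorted(range(k), key=lambda i: (mean_r[i], models[i].model_id))
    return True, models[order[0]], rmsds


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -12
_aligner.extend_gap_score = -1


def _sequence_correspondence(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """0-based residue index pairs from a global sequence alignment."""
    sa = "".join(c if c in "ACDEFGHIKLMNPQRSTVWYBZX" else "X" for c in seq_a.upper())
    sb = "".join(c if c in "ACDEFGHIKLMNPQRSTVWYBZX" else "X" for c in seq_b.upper())
    aln = _aligner.align(sa, sb)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


@dataclass(frozen=True)
class ScreenResult:
    candidate_id: str
    n_corresponded: int
    rmsd: float | None
    verdict: str  # positive | negative
    reason: str


def structural_ortholog_screen(
    query_domain: StructureModel,
    candidates: Sequence[StructureModel],
    accept_rmsd_max: float = 3.0,
    min_corresponded_fraction: float = 0.5,
) -> list[ScreenResult]:
    """Accept candidates whose domain superposes onto the query domain.

    Correspondence comes from a global sequence alignment of the domain
    sequences (aligned non-gap pairs only); a candidate is positive iff at
    least min_corresponded_fraction of the shorter domain is corresponded
    and the Kabsch RMSD over corresponded C-alphas is strictly below
    accept_rmsd_max.
    """
    results = []
    for cand in candidates:
        pairs = _sequence_correspondence(query_domain.sequence, cand.sequence)
        shorter = min(len(query_domain), len(cand))
        if len(pairs) < max(3, int(np.ceil(min_corresponded_fraction * shorter))):
            results.append(
                ScreenResult(cand.model_id, len(pairs), None, "negative",
                             "insufficient correspondence")
            )
            continue
        _, _, rmsd = kabsch_superpose(query_domain.coords, cand.coords, pairs)
        if rmsd < accept_rmsd_max:
            results.append(
                ScreenResult(cand.model_id, len(pairs), rmsd, "positive",
                             f"rmsd {rmsd:.2f} < {accept_rmsd_max:g}")
            )
        else:
            results.append(
                ScreenResult(cand.model_id, len(pairs), rmsd, "negative",
                             f"rmsd {rmsd:.2f} >= {accept_rmsd_max:g}")
            )
    return results


@dataclass(frozen=True)
class AnnotatedCandidate:
    """A candidate protein with its ordered domain labels and length."""

    candidate_id: str
    domains: tuple[str, ...]
    length: int


def _is_subsequence(needle: Sequence[str], haystack: Sequence[str]) -> bool:
    it = iter(haystack)
    return all(any(x == n for x in it) for n in needle)


def filter_by_topology_and_length(
    candidates: Sequence[AnnotatedCandidate],
    required_topology: Sequence[str],
    min_length: int | None = None,
) -> list[AnnotatedCandidate]:
    """Keep candidates whose domain order contains the required topology as
    a subsequence and whose length is >= min_length (strictly excluding
    shorter candidates)."""
    out = []
    for cand in candidates:
        if min_length is not None and cand.length < min_length:
            continue
        if _is_subsequence(tuple(required_topology), cand.domains):
            out.append(cand)
    return out
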