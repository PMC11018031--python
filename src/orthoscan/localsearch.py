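"""Local-alignment search engine.

Optimal local alignments under affine gaps (Gotoh recurrences), Waterman-
Eggert style non-intersecting suboptimal alignments, Karlin-Altschul score
statistics, and whole-database search with per-organism ranking.

Tie-breaking is fully specified so that results are platform-stable: among
equal-scoring cells the alignment ending at the smallest (q_end, s_end)
lexicographically wins, and traceback prefers diagonal moves over gap moves
(and gaps in the subject over gaps in the query).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .db import ProteinDatabase
from .scoring import DEFAULT_SCHEME, ScoringScheme, encode

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

_NEG = -(10**9)


@njit(cache=True)
def _gotoh_fill(S, gap_open, gap_extend, mask):
    """Fill local-alignment DP matrices over a pair-score matrix S.

    S[i, j] is the score of matching query position i with subject position
    j (0-based); this serves both sequence-sequence search (substitution
    matrix lookups) and profile-sequence search (column log-odds). H[i, j]:
    best local alignment score ending at query i / subject j (1-based). E:
    alignments ending with a gap in the query (subject residue unmatched);
    F: ending with a gap in the subject. A gap of length k costs gap_open +
    k * gap_extend. Diagonal transitions into masked cells are forbidden,
    which is what makes repeated calls Waterman-Eggert style
    non-intersecting.
    """
    n = S.shape[0]
    m = S.shape[1]
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    E = np.full((n + 1, m + 1), -1e18, dtype=np.float64)
    F = np.full((n + 1, m + 1), -1e18, dtype=np.float64)
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = E[i][j - 1] - gap_extend
            ho = H[i][j - 1] - first
            if ho > e:
                e = ho
            E[i][j] = e
            f = F[i - 1][j] - gap_extend
            vo = H[i - 1][j] - first
            if vo > f:
                f = vo
            F[i][j] = f
            best = 0.0
            if not mask[i - 1][j - 1]:
                d = H[i - 1][j - 1] + S[i - 1][j - 1]
                if d > best:
                    best = d
            if f > best:
                best = f
            if e > best:
                best = e
            H[i][j] = best
    return H, E, F


@dataclass(frozen=True)
class HSP:
    """A scored local alignment (high-scoring segment pair)."""

    query_id: str
    subject_id: str
    subject_organism: str
    q_start: int  # 1-based inclusive
    q_end: int
    s_start: int
    s_end: int
    raw_score: int
    aligned_pairs: tuple[tuple[int, int], ...]
    bit_score: float = float("nan")
    evalue: float = float("inf")

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    @property
    def q_span(self) -> int:
        """Number of query residues spanned (gap columns contribute nothing)."""
        return self.q_end - self.q_start + 1

    def identity_pct(self, query: str, subject: str) -> float:
        same = sum(
            1
            for qp, sp in self.aligned_pairs
            if query[qp - 1].upper() == subject[sp - 1].upper()
        )
        ncols = len(self.aligned_pairs)
        return 100.0 * same / ncols if ncols else 0.0


@dataclass
class Hit:
    """All HSPs of one query-subject pair plus summary statistics."""

    subject_id: str
    hsps: list[HSP]
    coverage_pct: float | None = None

    @property
    def best_bit(self) -> float:
        return max(h.bit_score for h in self.hsps)

    @property
    def best_evalue(self) -> float:
        return min(h.evalue for h in self.hsps)


@dataclass
class HitSet:
    """Per-organism ranked hit lists for one query."""

    query_id: str
    by_organism: dict[str, list[Hit]] = field(default_factory=dict)

    def sort(self) -> None:
        for hits in self.by_organism.values():
            hits.sort(key=lambda h: (-h.best_bit, h.best_evalue, h.subject_id))

    def all_hits(self):
        for organism, hits in self.by_organism.items():
            for hit in hits:
                yield organism, hit

    @property
    def n_hits(self) -> int:
        return sum(len(v) for v in self.by_organism.values())


def _traceback(H, E, F, S, gap_open, gap_extend, mask, i, j):
    """Recover one alignment path ending at (i, j); returns aligned pairs."""
    first = gap_open + gap_extend
    pairs = []
    state = 0  # 0=H, 1=E (gap in query), 2=F (gap in subject)
    while True:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if (
                not mask[i - 1, j - 1]
                and h == H[i - 1, j - 1] + S[i - 1, j - 1]
            ):
                pairs.append((i, j))
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 2:
            if F[i, j] == H[i - 1, j] - first:
                state = 0
            # else: stay in F (gap extension)
            i -= 1
        else:
            if E[i, j] == H[i, j - 1] - first:
                state = 0
            j -= 1
    pairs.reverse()
    return pairs


def align_scores_local(S: np.ndarray, gap_open: float, gap_extend: float, mask=None):
    """Optimal local alignment over an arbitrary pair-score matrix.

    Returns (score, aligned 1-based (i, j) pairs); score 0 and an empty
    path when no positive-scoring cell exists. Shared by sequence-sequence
    and profile-sequence search.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    if mask is None:
        mask = np.zeros(S.shape, dtype=np.bool_)
    H, E, F = _gotoh_fill(S, float(gap_open), float(gap_extend), mask)
    score = float(H.max())
    if score <= 0:
        return 0.0, []
    flat = int(np.argmax(H))  # row-major: smallest (q_end, s_end) among ties
    i, j = divmod(flat, H.shape[1])
    pairs = _traceback(H, E, F, S, gap_open, gap_extend, mask, i, j)
    return score, pairs


def _pair_scores(q_enc, s_enc, scheme: ScoringScheme) -> np.ndarray:
    return scheme.substitution_matrix[q_enc][:, s_enc].astype(np.float64)


def _align_once(q_enc, s_enc, scheme: ScoringScheme, mask):
    score, pairs = align_scores_local(
        _pair_scores(q_enc, s_enc, scheme), scheme.gap_open, scheme.gap_extend, mask
    )
    return int(round(score)), pairs


def _make_hsp(query_id, subject_id, organism, score, pairs) -> HSP:
    qs = [p[0] for p in pairs]
    ss = [p[1] for p in pairs]
    return HSP(
        query_id=query_id,
        subject_id=subject_id,
        subject_organism=organism,
        q_start=min(qs),
        q_end=max(qs),
        s_start=min(ss),
        s_end=max(ss),
        raw_score=score,
        aligned_pairs=tuple(pairs),
    )


def smith_waterman(
    query: str,
    subject: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
    subject_organism: str = "",
) -> HSP | None:
    """Optimal local alignment under affine gaps; None if no positive cell."""
    q_enc = encode(query)
    s_enc = encode(subject)
    mask = np.zeros((len(query), len(subject)), dtype=np.bool_)
    score, pairs = _align_once(q_enc, s_enc, scheme, mask)
    if score <= 0:
        return None
    return _make_hsp(query_id, subject_id, subject_organism, score, pairs)


def waterman_eggert(
    query: str,
    subject: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_hsps: int = 5,
    min_raw_score: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
    subject_organism: str = "",
) -> list[HSP]:
    """Up to max_hsps local alignments sharing no aligned (q, s) cell.

    Each successive alignment is found after masking the aligned cells of
    the previous ones, so scores are non-increasing and the first element
    equals the smith_waterman optimum.
    """
    if max_hsps < 1:
        raise ValueError("max_hsps must be >= 1")
    q_enc = encode(query)
    s_enc = encode(subject)
    mask = np.zeros((len(query), len(subject)), dtype=np.bool_)
    out: list[HSP] = []
    for _ in range(max_hsps):
        score, pairs = _align_once(q_enc, s_enc, scheme, mask)
        if score <= 0 or score < min_raw_score or not pairs:
            break
        out.append(_make_hsp(query_id, subject_id, subject_organism, score, pairs))
        for qp, sp in pairs:
            mask[qp - 1, sp - 1] = True
    return out


def score_statistics(
    raw_score: int, m: int, n: int, scheme: ScoringScheme = DEFAULT_SCHEME
) -> tuple[float, float]:
    """Karlin-Altschul bit score and E-value for a raw alignment score.

    bit = (lambda * S - ln K) / ln 2 ; E = m * n * 2 ** (-bit).
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    bit = (scheme.lambda_ * raw_score - math.log(scheme.K)) / math.log(2)
    evalue = m * n * 2.0 ** (-bit)
    return bit, evalue


def min_significant_raw_score(
    m: int, n: int, evalue_max: float, scheme: ScoringScheme = DEFAULT_SCHEME
) -> int:
    """Smallest raw score whose E-value is <= evalue_max."""
    bit = math.log2(m * n / evalue_max)
    return math.ceil((bit * math.log(2) + math.log(scheme.K)) / scheme.lambda_)


def search_database(
    query: str,
    db: ProteinDatabase,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    evalue_max: float = 0.1,
    per_subject_hsps: int = 5,
    query_id: str = "query",
    exclude_ids: frozenset[str] | set[str] = frozenset(),
) -> HitSet:
    """Search a query against every database record.

    E-values use n = total residue count of the database. Subjects whose
    best E-value exceeds evalue_max are discarded; survivors carry up to
    per_subject_hsps non-intersecting HSPs for the coverage statistic.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    n_total = db.total_residues
    m = len(query)
    min_raw = min_significant_raw_score(m, n_total, evalue_max, scheme)
    hitset = HitSet(query_id=query_id)
    for rec in db:
        if rec.id in exclude_ids:
            continue
        hsps = waterman_eggert(
            query,
            rec.seq,
            scheme,
            max_hsps=per_subject_hsps,
            min_raw_score=min_raw,
            query_id=query_id,
            subject_id=rec.id,
            subject_organism=rec.organism,
        )
        if not hsps:
            continue
        hsps = [
            replace(h, bit_score=bit, evalue=ev)
            for h in hsps
            for bit, ev in [score_statistics(h.raw_score, m, n_total, scheme)]
        ]
        hitset.by_organism.setdefault(rec.organism, []).append(
            Hit(subject_id=rec.id, hsps=hsps)
        )
    hitset.sort()
    return hitset


def hitset_to_rows(hitset: HitSet, db: ProteinDatabase, query: str) -> list[dict]:
    """Tabular (BLAST-outfmt6-like) rows for a hit set."""
    rows = []
    for organism, hit in hitset.all_hits():
        subject = db[hit.subject_id].seq
        for h in hit.hsps:
            rows.append(
                {
                    "qseqid": hitset.query_id,
                    "sseqid": hit.subject_id,
                    "organism": organism,
                    "pident": round(h.identity_pct(query, subject), 2),
                    "length": len(h.aligned_pairs),
                    "qstart": h.q_start,
                    "qend": h.q_end,
                    "sstart": h.s_start,
                    "send": h.s_end,
                    "bitscore": round(h.bit_score, 2),
                    "evalue": h.evalue,
                    "coverage_pct": hit.coverage_pct,
                }
            )
    return rows
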