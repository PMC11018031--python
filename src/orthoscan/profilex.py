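"""Progressive MSA, gap-fraction trimming, position-specific profiles, and
the iterative expansion loop.

The profile is a position-specific log-odds model (half-bit units, matching
the BLOSUM62 scale) with substitution-matrix-derived pseudocounts, searched
against sequences with the same affine-gap local alignment engine used for
sequence-sequence search. Expansion alternates profile search with reverse
confirmation against the original database and repeats until an iteration
adds no new members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .db import ProteinDatabase
from .localsearch import (
    Hit,
    HitSet,
    HSP,
    align_scores_local,
    search_database,
)
from .orthocall import OrthologCall, OrthologTable, PipelineConfig, query_coverage
from .scoring import AMINO_ACIDS, AMBIGUOUS_INDEX, BACKGROUND, DEFAULT_SCHEME, encode

GAP = "-"


@dataclass
class MSA:
    """A multiple sequence alignment as ordered (id, gapped sequence) rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must match")
        if self.rows:
            ncols = len(self.rows[0])
            if any(len(r) != ncols for r in self.rows):
                raise ValueError("all gapped sequences must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def gap_fractions(self) -> np.ndarray:
        if not self.rows:
            return np.zeros(0)
        arr = np.array([list(r) for r in self.rows])
        return (arr == GAP).mean(axis=0)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MSA":
        ids, rows = [], []
        with open(path) as fh:
            seq: list[str] = []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if seq:
                        rows.append("".join(seq))
                        seq = []
                    ids.append(line[1:].split()[0])
                elif line:
                    seq.append(line)
            if seq:
                rows.append("".join(seq))
        return cls(ids, rows)


def _column_frequencies(rows: list[str]) -> np.ndarray:
    """(n_cols, 20) residue frequencies per column, normalised by the number
    of rows so gap columns carry proportionally less weight."""
    ncols = len(rows[0])
    freq = np.zeros((ncols, 20))
    for row in rows:
        enc = encode(row.replace(GAP, "X") if GAP in row else row)
        for c, code in enumerate(row):
            if code != GAP and enc[c] != AMBIGUOUS_INDEX:
                freq[c, enc[c]] += 1.0
    return freq / len(rows)


def _profile_profile_align(rows_a: list[str], rows_b: list[str],
                           scheme=DEFAULT_SCHEME) -> tuple[list[str], list[str]]:
    """Global affine alignment of two alignment blocks.

    Column pairs are scored by the expected BLOSUM62 score between their
    residue distributions; gaps in existing columns simply reduce the
    column weight.
    """
    fa = _column_frequencies(rows_a)
    fb = _column_frequencies(rows_b)
    B = scheme.substitution_matrix[:20, :20].astype(float)
    S = fa @ B @ fb.T
    na, nb = S.shape
    gap_open = float(scheme.gap_open)
    gap_ext = float(scheme.gap_extend)
    NEG = -1e18
    H = np.full((na + 1, nb + 1), NEG)
    E = np.full((na + 1, nb + 1), NEG)
    F = np.full((na + 1, nb + 1), NEG)
    H[0, 0] = 0.0
    first = gap_open + gap_ext
    for j in range(1, nb + 1):
        E[0, j] = -(gap_open + gap_ext * j)
        H[0, j] = E[0, j]
    for i in range(1, na + 1):
        F[i, 0] = -(gap_open + gap_ext * i)
        H[i, 0] = F[i, 0]
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            E[i, j] = max(E[i, j - 1] - gap_ext, H[i, j - 1] - first)
            F[i, j] = max(F[i - 1, j] - gap_ext, H[i - 1, j] - first)
            H[i, j] = max(H[i - 1, j - 1] + S[i - 1, j - 1], E[i, j], F[i, j])
    # traceback, preferring diagonal then vertical (block A) then horizontal
    ops = []
    i, j = na, nb
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[i - 1, j - 1]:
                ops.append("D")
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 2:
            ops.append("U")
            if F[i, j] == H[i - 1, j] - first:
                state = 0
            i -= 1
        else:
            ops.append("L")
            if E[i, j] == H[i, j - 1] - first:
                state = 0
            j -= 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == "D":
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ia])
            for k, row in enumerate(rows_b):
                out_b[k].append(row[ib])
            ia += 1
            ib += 1
        elif op == "U":
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ia])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, row in enumerate(rows_b):
                out_b[k].append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _pairwise_distance(a: str, b: str, scheme=DEFAULT_SCHEME) -> float:
    """1 - identity over matched columns of a pairwise global alignment."""
    (ra,), (rb,) = _profile_profile_align([a], [b], scheme)
    matched = same = 0
    for x, y in zip(ra, rb):
        if x != GAP and y != GAP:
            matched += 1
            if x == y:
                same += 1
    return 1.0 - (same / matched if matched else 0.0)


def progressive_align(sequences: list[tuple[str, str]],
                      scheme=DEFAULT_SCHEME) -> MSA:
    """Progressive MSA: identity distances, UPGMA guide tree, profile-
    profile merges up the tree. Deterministic; ties resolved by input order."""
    if not sequences:
        raise ValueError("no sequences to align")
    if len(sequences) == 1:
        return MSA([sequences[0][0]], [sequences[0][1]])
    n = len(sequences)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _pairwise_distance(sequences[i][1], sequences[j][1], scheme)
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([sequences[i][0]], [sequences[i][1]]) for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        merged_a, merged_b = _profile_profile_align(rows_a, rows_b, scheme)
        clusters[n + k] = (ids_a + ids_b, merged_a + merged_b)
    ids, rows = clusters.popitem()[1]
    # restore input order
    order = {sid: i for i, (sid, _) in enumerate(sequences)}
    pairs = sorted(zip(ids, rows), key=lambda p: order[p[0]])
    return MSA([p[0] for p in pairs], [p[1] for p in pairs])


def trim_columns(msa: MSA, max_gap_fraction: float) -> MSA:
    """Remove every column whose gap fraction exceeds max_gap_fraction
    (retained when the fraction is <= the threshold, inclusive)."""
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    if msa.n_seqs == 0:
        raise ValueError("empty MSA")
    keep = msa.gap_fractions() <= max_gap_fraction
    rows = ["".join(ch for ch, k in zip(row, keep) if k) for row in msa.rows]
    return MSA(list(msa.ids), rows)


def _conditional_substitution_probs(scheme=DEFAULT_SCHEME) -> np.ndarray:
    """q[j | a]: probability of residue j in a column whose observed residue
    is a, derived from the substitution matrix (half-bit log-odds)."""
    B = scheme.substitution_matrix[:20, :20].astype(float)
    q = BACKGROUND[np.newaxis, :] * 2.0 ** (B / 2.0)  # rows: a, cols: j
    return q / q.sum(axis=1, keepdims=True)


@dataclass
class AlignmentProfile:
    """Per-column log-odds scores (half-bit units) built from an MSA."""

    source_msa_id: str
    scores: np.ndarray  # (n_cols, 20) half-bits
    occupancy: np.ndarray  # (n_cols,), 1 - gap fraction
    pseudocount: float
    member_ids: tuple[str, ...]

    @property
    def n_cols(self) -> int:
        return self.scores.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.scores, columns=list(AMINO_ACIDS))
        df.insert(0, "occupancy", self.occupancy)
        df.to_csv(path, sep="\t", index_label="column", float_format="%.4f")


def build_profile(
    msa: MSA,
    pseudocount: float = 1.0,
    source_msa_id: str = "msa",
    scheme=DEFAULT_SCHEME,
) -> AlignmentProfile:
    """Position-specific log-odds profile with matrix-derived pseudocounts.

    Column frequencies are mixed with pseudocount mass distributed
    according to the substitution matrix's conditional probabilities
    (weight = pseudocount effective sequences), then scored as half-bit
    log-odds against the background frequencies.
    """
    if msa.n_seqs == 0:
        raise ValueError("empty MSA")
    q = _conditional_substitution_probs(scheme)
    ncols = msa.n_cols
    counts = np.zeros((ncols, 20))
    gaps = np.zeros(ncols)
    for row in msa.rows:
        for c, ch in enumerate(row):
            if ch == GAP:
                gaps[c] += 1
            else:
                idx = encode(ch)[0]
                if idx != AMBIGUOUS_INDEX:
                    counts[c, idx] += 1
    n_obs = counts.sum(axis=1)
    scores = np.zeros((ncols, 20))
    for c in range(ncols):
        if n_obs[c] == 0:
            continue
        f_obs = counts[c] / n_obs[c]
        g = f_obs @ q
        f = (counts[c] + pseudocount * g) / (n_obs[c] + pseudocount)
        scores[c] = 2.0 * np.log2(f / BACKGROUND)
    occupancy = 1.0 - gaps / msa.n_seqs
    return AlignmentProfile(
        source_msa_id=source_msa_id,
        scores=scores,
        occupancy=occupancy,
        pseudocount=pseudocount,
        member_ids=tuple(msa.ids),
    )


def profile_search(
    profile: AlignmentProfile,
    db: ProteinDatabase,
    cfg: PipelineConfig,
    restrict_organisms: set[str] | None = None,
) -> HitSet:
    """Local profile-sequence search against every non-member record.

    Hits are ranked per organism by raw profile score (half-bit units; no
    E-value calibration is attempted for profile scores) and truncated to
    the configured top_k.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    members = set(profile.member_ids)
    # score for the ambiguity catch-all: worst score of the column
    ext = np.concatenate(
        [profile.scores, profile.scores.min(axis=1, keepdims=True)], axis=1
    )
    hitset = HitSet(query_id=profile.source_msa_id)
    scheme = cfg.scheme
    for rec in db:
        if rec.id in members:
            continue
        if restrict_organisms is not None and rec.organism not in restrict_organisms:
            continue
        s_enc = encode(rec.seq)
        S = ext[:, s_enc]
        score, pairs = align_scores_local(S, scheme.gap_open, scheme.gap_extend)
        if score <= 0 or not pairs:
            continue
        qs = [p[0] for p in pairs]
        ss = [p[1] for p in pairs]
        hsp = HSP(
            query_id=profile.source_msa_id,
            subject_id=rec.id,
            subject_organism=rec.organism,
            q_start=min(qs),
            q_end=max(qs),
            s_start=min(ss),
            s_end=max(ss),
            raw_score=int(round(score)),
            aligned_pairs=tuple(pairs),
            bit_score=score / 2.0,  # half-bits -> bits
            evalue=float("inf"),
        )
        hitset.by_organism.setdefault(rec.organism, []).append(
            Hit(subject_id=rec.id, hsps=[hsp])
        )
    hitset.sort()
    for org in list(hitset.by_organism):
        hitset.by_organism[org] = hitset.by_organism[org][: cfg.top_k]
    return hitset


def member_self_scores(profile: AlignmentProfile, db: ProteinDatabase,
                       cfg: PipelineConfig) -> dict[str, float]:
    """Raw profile score of each member's own ungapped sequence."""
    ext = np.concatenate(
        [profile.scores, profile.scores.min(axis=1, keepdims=True)], axis=1
    )
    out = {}
    for mid in profile.member_ids:
        s_enc = encode(db[mid].seq)
        score, _ = align_scores_local(
            ext[:, s_enc], cfg.scheme.gap_open, cfg.scheme.gap_extend
        )
        out[mid] = score
    return out


def _reverse_member_confirm(
    candidate_id: str,
    members: set[str],
    db: ProteinDatabase,
    cfg: PipelineConfig,
) -> tuple[bool, str, float | None]:
    """Reverse-search confirmation at the profile stage.

    The candidate is searched against the original database (itself
    excluded); reverse hits are filtered by E-value and query coverage as
    in the forward direction, then the candidate is accepted iff the top
    surviving reverse hit of at least one organism is a current profile
    member. Returns (accept, top-hit summary, coverage of the deciding hit).
    """
    cand = db[candidate_id]
    rev = search_database(
        cand.seq,
        db,
        cfg.scheme,
        evalue_max=cfg.evalue_max,
        per_subject_hsps=cfg.per_subject_hsps,
        query_id=candidate_id,
        exclude_ids={candidate_id},
    )
    from .orthocall import annotate_coverage, filter_top_hits

    annotate_coverage(rev, len(cand.seq))
    rev = filter_top_hits(rev, len(cand.seq), cfg)
    tops = []
    for organism in sorted(rev.by_organism):
        hits = rev.by_organism[organism]
        if hits:
            tops.append((organism, hits[0]))
    for organism, hit in tops:
        if hit.subject_id in members:
            return True, hit.subject_id, hit.coverage_pct
    if tops:
        best = max(tops, key=lambda oh: oh[1].best_bit)
        return False, best[1].subject_id, best[1].coverage_pct
    return False, "", None


def expand_iteratively(
    confirmed: OrthologTable,
    db: ProteinDatabase,
    cfg: PipelineConfig,
    log: list | None = None,
) -> OrthologTable:
    """Iterative profile expansion until convergence.

    Per seed query: align the current members (untrimmed alignment), build
    a profile, search organisms that still lack a member, take the top_k
    candidates per organism, and accept a candidate iff the top reverse hit
    of the candidate against the original database (candidate itself
    excluded, E-value filter applied) is one of the current members. The
    loop stops when an iteration adds nothing or max_iterations is reached;
    membership only ever grows, so termination is guaranteed.
    """
    if len(confirmed) == 0:
        raise ValueError("confirmed table must be non-empty")
    table = OrthologTable(list(confirmed))
    all_organisms = set(db.organisms)
    for query_id in sorted({c.query_id for c in confirmed}):
        members = [c.subject_id for c in table.subjects_for(query_id)]
        for iteration in range(1, cfg.max_iterations + 1):
            covered_orgs = {db[m].organism for m in members}
            remaining = all_organisms - covered_orgs
            if not remaining:
                break
            msa = progressive_align([(m, db[m].seq) for m in members], cfg.scheme)
            profile = build_profile(
                msa, cfg.pseudocount, source_msa_id=query_id, scheme=cfg.scheme
            )
            hits = profile_search(profile, db, cfg, restrict_organisms=remaining)
            added = 0
            for organism in sorted(hits.by_organism):
                for hit in hits.by_organism[organism]:
                    accept, top_id, rev_cov = _reverse_member_confirm(
                        hit.subject_id, set(members), db, cfg
                    )
                    if log is not None:
                        log.append(
                            {
                                "stage": "profile",
                                "query_id": query_id,
                                "subject_id": hit.subject_id,
                                "organism": organism,
                                "iteration": iteration,
                                "profile_score": hit.hsps[0].raw_score,
                                "reverse_top_hit": top_id,
                                "reverse_coverage_pct": rev_cov,
                                "decision": "accept" if accept else "reject",
                            }
                        )
                    if accept and (query_id, hit.subject_id) not in table:
                        h = hit.hsps[0]
                        cov = 100.0 * (h.s_end - h.s_start + 1) / len(db[hit.subject_id].seq)
                        table.add(
                            OrthologCall(
                                query_id=query_id,
                                subject_id=hit.subject_id,
                                organism=organism,
                                coverage_pct=cov,
                                evidence_tier="profile",
                                iteration_found=iteration,
                            )
                        )
                        members.append(hit.subject_id)
                        added += 1
            if added == 0:
                break
    return table
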