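"""Gene-model rescue.

Six-frame translation of genomic regions around translated-search hits,
extraction of stop-to-stop candidate ORFs with genomic coordinates, fusion
of ORF fragments split across reading frames by sequencing indels (guided
by a homologous protein), and majority-rule indel correction of contigs
from a per-position pileup table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

_VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class GenomicRegion:
    """A nucleotide region, 1-based inclusive coordinates on its contig."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    sequence: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("sequence length must equal interval length")
        bad = set(self.sequence.upper()) - _VALID_NT
        if bad:
            raise ValueError(f"non-ACGTN characters: {sorted(bad)}")


@dataclass(frozen=True)
class OrfFragment:
    frame: int  # +1..+3, -1..-3
    peptide: str
    start: int  # genomic interval of the codons, 1-based inclusive
    end: int


def six_frame_translate(region: GenomicRegion) -> dict[int, str]:
    """Standard-code translation in all six frames.

    Frames +1..+3 read the given sequence with offsets 0..2; -1..-3 read
    the reverse complement the same way. Stops are rendered '*'; trailing
    partial codons are dropped.
    """
    seq = region.sequence.upper()
    if len(seq) < 3:
        raise ValueError("region too short to translate")
    rc = str(Seq(seq).reverse_complement())
    out: dict[int, str] = {}
    for f in (1, 2, 3):
        sub = seq[f - 1 :]
        sub = sub[: len(sub) - len(sub) % 3]
        out[f] = str(Seq(sub).translate())
        sub = rc[f - 1 :]
        sub = sub[: len(sub) - len(sub) % 3]
        out[-f] = str(Seq(sub).translate())
    return out


def _frame_to_genomic(frame: int, pep_start: int, pep_end: int, region_len: int
                      ) -> tuple[int, int]:
    """Map a 0-based peptide slice [pep_start, pep_end) in a frame back to
    1-based region-local nucleotide coordinates (always start <= end)."""
    f = abs(frame)
    nt_start = (f - 1) + 3 * pep_start  # 0-based on the read strand
    nt_end = (f - 1) + 3 * pep_end - 1
    if frame > 0:
        return nt_start + 1, nt_end + 1
    return region_len - nt_end, region_len - nt_start


def extract_candidate_orfs(
    region: GenomicRegion, min_len: int = 50
) -> list[OrfFragment]:
    """Stop-to-stop peptide stretches of at least min_len residues, with
    their region-local genomic coordinates."""
    frames = six_frame_translate(region)
    out = []
    for frame in (1, 2, 3, -1, -2, -3):
        pep = frames[frame]
        pos = 0
        for chunk in pep.split("*"):
            if len(chunk) >= min_len:
                g_start, g_end = _frame_to_genomic(
                    frame, pos, pos + len(chunk), len(region.sequence)
                )
                out.append(OrfFragment(frame, chunk, g_start, g_end))
            pos += len(chunk) + 1
    return out


def _local_alignment(a: str, b: str):
    from .localsearch import smith_waterman

    return smith_waterman(a, b)


def _aligned_genomic_span(f: OrfFragment, hsp) -> tuple[int, int]:
    """Genomic interval of the homolog-aligned part of a fragment."""
    if f.frame > 0:
        return f.start + 3 * (hsp.q_start - 1), f.start + 3 * hsp.q_end - 1
    return f.end - 3 * hsp.q_end + 1, f.end - 3 * (hsp.q_start - 1)


def fuse_frameshift_fragments(
    fragments: list[OrfFragment], homolog: str
) -> tuple[str, list[int]]:
    """Fuse ORF fragments from different reading frames into one protein.

    Fragments are ordered by genomic position; for each junction the
    crossover point on the homolog is chosen to maximize the number of
    homolog-matching residues kept from both sides (summed local-alignment
    support), duplicated junction residues are collapsed, and the fusion
    points (residue index in the fused product after which a junction
    occurs) are returned alongside the protein. Terminal residues outside
    the homolog alignment are trimmed: stop-to-stop ORFs carry frame noise
    at their edges and the homolog defines the gene-model boundaries.
    """
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments to fuse")
    pairs = []
    for f in fragments:
        hsp = _local_alignment(f.peptide, homolog)
        if hsp is None:
            raise ValueError(f"fragment at {f.start}-{f.end} does not align to homolog")
        pairs.append((f, hsp))
    # order by the genomic position of the aligned region (strand-aware);
    # homolog order must then be consistent or the fragments conflict
    pairs.sort(key=lambda fh: _aligned_genomic_span(*fh))
    h_starts = [h.s_start for _, h in pairs]
    h_ends = [h.s_end for _, h in pairs]
    if h_starts != sorted(h_starts) or h_ends != sorted(h_ends):
        raise ValueError(
            "fragments map to conflicting homolog regions (order inversion)"
        )
    frags = [f for f, _ in pairs]
    aligns = [h for _, h in pairs]
    junctions: list[int] = []
    prev = frags[0]
    prev_aln = aligns[0]
    # per alignment: homolog position -> (fragment position, match score)
    from .scoring import BLOSUM62, encode

    def _score_map(frag, aln):
        fe = encode(frag.peptide)
        he = encode(homolog)
        return {
            sp: (qp, int(BLOSUM62[fe[qp - 1], he[sp - 1]]))
            for qp, sp in aln.aligned_pairs
        }

    maps = [_score_map(f, a) for f, a in zip(frags, aligns)]
    fused = prev.peptide[prev_aln.q_start - 1 :]
    prev_c = 0
    for idx in range(1, len(frags)):
        nxt = frags[idx]
        nxt_aln = aligns[idx]
        a_map, b_map = maps[idx - 1], maps[idx]
        lo = nxt_aln.s_start
        hi = prev_aln.s_end
        best = None
        # crossover c: keep prev residues aligned to homolog <= c, next > c;
        # choose c maximizing the summed substitution score of what is kept
        # (monotone across junctions)
        for c in range(max(min(lo, hi) - 1, prev_c), max(lo, hi) + 1):
            left = sum(sc for sp, (_, sc) in a_map.items() if sp <= c)
            right = sum(sc for sp, (_, sc) in b_map.items() if sp > c)
            key = (left + right, -abs(c - (lo + hi) // 2))
            if best is None or key > best[0]:
                best = (key, c)
        if best is None:
            raise ValueError("no admissible crossover point at a junction")
        c = best[1]
        prev_c = c
        left_cut = max([a_map[sp][0] for sp in a_map if sp <= c], default=0)
        right_from = min([b_map[sp][0] for sp in b_map if sp > c], default=1)
        fused = fused[: len(fused) - (len(prev.peptide) - left_cut)]
        junctions.append(len(fused))
        fused = fused + nxt.peptide[right_from - 1 :]
        prev = nxt
        prev_aln = nxt_aln
    fused = fused[: len(fused) - (len(prev.peptide) - prev_aln.q_end)]
    return fused, junctions


def rescue_gene_model(
    contig: str,
    homolog: str,
    min_orf_len: int = 25,
    max_fragments: int = 4,
) -> tuple[str, dict]:
    """Reconstruct a protein from a contig using a homolog as the guide.

    Extracts stop-to-stop ORFs in all six frames, keeps those that align
    locally to the homolog (best-scoring first, up to max_fragments), and
    fuses them across frameshifts. Returns the protein and a metadata dict
    (fragments used, fusion points).
    """
    from .localsearch import smith_waterman

    region = GenomicRegion("contig", 1, len(contig), "+", contig.upper())
    frags = extract_candidate_orfs(region, min_len=min_orf_len)
    scored = []
    for f in frags:
        hsp = smith_waterman(f.peptide, homolog)
        if hsp is not None:
            scored.append((f, hsp))
    if not scored:
        raise ValueError("no ORF aligns to the homolog")
    # best collinear chain over the homolog-ALIGNED genomic spans: a
    # stop-to-stop ORF can run far beyond its homologous core, so ordering
    # must use the coordinates of the aligned region, not the whole ORF
    entries = []
    for f, hsp in scored:
        if f.frame > 0:
            g_lo = f.start + 3 * (hsp.q_start - 1)
            g_hi = f.start + 3 * hsp.q_end - 1
        else:
            g_hi = f.end - 3 * (hsp.q_start - 1)
            g_lo = f.end - 3 * hsp.q_end + 1
        entries.append((f, hsp, g_lo, g_hi))
    entries.sort(key=lambda e: (e[2], e[3]))
    n = len(entries)
    total = [e[1].raw_score for e in entries]
    parent = [-1] * n
    for j in range(n):
        _, hj, glo_j, ghi_j = entries[j]
        for i in range(j):
            _, hi_, glo_i, ghi_i = entries[i]
            if (
                glo_j > glo_i
                and ghi_j > ghi_i
                and hj.s_start > hi_.s_start
                and hj.s_end > hi_.s_end + 9  # must add >=10 new homolog residues
                and total[i] + entries[j][1].raw_score > total[j]
            ):
                total[j] = total[i] + entries[j][1].raw_score
                parent[j] = i
    j = max(range(n), key=lambda k: total[k])
    chain = []
    while j != -1:
        chain.append(entries[j][0])
        j = parent[j]
    chain.reverse()
    kept = chain[:max_fragments]
    if len(kept) == 1:
        f = kept[0]
        hsp = smith_waterman(f.peptide, homolog)
        protein = f.peptide[hsp.q_start - 1 : hsp.q_end]
        return protein, {"n_fragments": 1, "fusion_points": []}
    protein, junctions = fuse_frameshift_fragments(kept, homolog)
    return protein, {"n_fragments": len(kept), "fusion_points": junctions}


@dataclass
class PileupColumn:
    """Read evidence at one contig position (1-based)."""

    pos: int
    ref: str
    base_counts: dict[str, int] = field(default_factory=dict)
    insertions: dict[str, int] = field(default_factory=dict)
    deletions: int = 0

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.deletions


@dataclass(frozen=True)
class IndelEdit:
    pos: int
    kind: str  # insertion | deletion
    sequence: str
    support: float


def correct_indels_from_pileup(
    contig: str,
    pileup: list[PileupColumn],
    min_depth: int = 5,
    min_fraction: float = 0.5,
) -> tuple[str, list[IndelEdit]]:
    """Majority-rule indel correction.

    At every pileup position with depth >= min_depth, an insertion (placed
    after the position) or a deletion (of the position's base) is applied
    iff its supporting count exceeds min_fraction of the depth. Edits are
    applied right-to-left so earlier coordinates stay valid.
    """
    for col in pileup:
        if not 1 <= col.pos <= len(contig):
            raise ValueError(f"pileup position {col.pos} outside contig")
    edits: list[IndelEdit] = []
    for col in sorted(pileup, key=lambda c: -c.pos):
        depth = col.depth
        if depth < min_depth:
            continue
        candidates: list[IndelEdit] = []
        if col.insertions:
            ins_seq, ins_n = max(col.insertions.items(), key=lambda kv: (kv[1], kv[0]))
            if ins_n / depth > min_fraction:
                candidates.append(
                    IndelEdit(col.pos, "insertion", ins_seq, ins_n / depth)
                )
        if col.deletions / depth > min_fraction if depth else False:
            candidates.append(
                IndelEdit(col.pos, "deletion", contig[col.pos - 1], col.deletions / depth)
            )
        if len(candidates) > 1:
            raise ValueError(
                f"conflicting majority edits at position {col.pos}: "
                + ", ".join(c.kind for c in candidates)
            )
        if candidates:
            edits.append(candidates[0])
    corrected = contig
    for e in edits:  # already right-to-left
        if e.kind == "insertion":
            corrected = corrected[: e.pos] + e.sequence + corrected[e.pos :]
        else:
            corrected = corrected[: e.pos - 1] + corrected[e.pos :]
    return corrected, edits


def read_pileup_tsv(path: str | Path) -> list[PileupColumn]:
    """Parse the simplified pileup TSV: pos, ref, A, C, G, T, then optional
    ``ins:<seq>:<count>`` fields and ``del:<count>``."""
    cols = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            col = PileupColumn(
                pos=int(parts[idx["pos"]]),
                ref=parts[idx["ref"]],
                base_counts={
                    b: int(parts[idx[b]]) for b in "ACGT" if b in idx
                },
            )
            for extra in parts[len([k for k in ("pos", "ref", "A", "C", "G", "T") if k in idx]):]:
                if extra.startswith("ins:"):
                    _, seq, cnt = extra.split(":")
                    col.insertions[seq] = int(cnt)
                elif extra.startswith("del:"):
                    col.deletions = int(extra.split(":")[1])
            cols.append(col)
    return cols
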