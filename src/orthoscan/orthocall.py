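"""Reciprocal-best-hit orthology calculus.

Implements the coverage statistic (percent of query residues covered by
non-overlapping local alignments, gaps removed), top-k per-organism hit
filtering, reciprocal confirmation against the original database, and the
full best-reciprocal-BLAST (BRB) stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .db import ProteinDatabase
from .localsearch import HSP, Hit, HitSet, search_database
from .scoring import DEFAULT_SCHEME, ScoringScheme


@dataclass
class PipelineConfig:
    """All numeric thresholds of the orthology pipeline in one place.

    Defaults are the working thresholds of the procedure: E-value 0.1,
    top five hits per organism, >=30% query coverage, MSA columns trimmed
    when gapped in more than 25% of sequences (75% as the relaxed variant),
    structural consensus below 5 A RMSD, structural acceptance below 3 A,
    and an optional minimum candidate length (e.g. 1000 residues) for
    domain-promiscuous families.
    """

    evalue_max: float = 0.1
    top_k: int = 5
    min_coverage_pct: float = 30.0
    trim_max_gap_fraction: float = 0.25
    min_length_residues: int | None = None
    consensus_rmsd_max: float = 5.0
    accept_rmsd_max: float = 3.0
    max_iterations: int = 10
    per_subject_hsps: int = 5
    pseudocount: float = 1.0
    seed: int = 0
    scheme: ScoringScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 <= self.min_coverage_pct <= 100:
            raise ValueError("min_coverage_pct must be in [0, 100]")
        if not 0 <= self.trim_max_gap_fraction <= 1:
            raise ValueError("trim_max_gap_fraction must be in [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML (or flat key: value) config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass(frozen=True)
class OrthologCall:
    """One accepted ortholog with its evidence tier and confidence."""

    query_id: str
    subject_id: str
    organism: str
    coverage_pct: float | None
    evidence_tier: str  # reciprocal | profile | structural
    iteration_found: int
    confidence: str = "high"  # high | low
    rmsd: float | None = None


class OrthologTable:
    """Accepted ortholog calls, keyed by (query_id, subject_id)."""

    def __init__(self, calls: Iterable[OrthologCall] = ()):
        self.calls: list[OrthologCall] = []
        self._keys: set[tuple[str, str]] = set()
        for c in calls:
            self.add(c)

    def add(self, call: OrthologCall) -> bool:
        key = (call.query_id, call.subject_id)
        if key in self._keys:
            return False
        self.calls.append(call)
        self._keys.add(key)
        return True

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._keys

    def subjects_for(self, query_id: str) -> list[OrthologCall]:
        return [c for c in self.calls if c.query_id == query_id]

    def set_confidence(self, query_id: str, subject_id: str, confidence: str) -> None:
        for i, c in enumerate(self.calls):
            if c.query_id == query_id and c.subject_id == subject_id:
                self.calls[i] = OrthologCall(
                    c.query_id, c.subject_id, c.organism, c.coverage_pct,
                    c.evidence_tier, c.iteration_found, confidence, c.rmsd,
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query_id": c.query_id,
                    "organism": c.organism,
                    "subject_id": c.subject_id,
                    "coverage_pct": c.coverage_pct,
                    "evidence_tier": c.evidence_tier,
                    "iteration": c.iteration_found,
                    "confidence": c.confidence,
                    "rmsd": c.rmsd,
                }
                for c in self.calls
            ],
            columns=[
                "query_id", "organism", "subject_id", "coverage_pct",
                "evidence_tier", "iteration", "confidence", "rmsd",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def query_coverage(hsps: Sequence[HSP], query_length: int) -> float:
    """Percent of the query covered by non-overlapping local alignments.

    HSPs are taken best-score first (ties: longer query span, then smaller
    q_start) and accepted greedily iff their query interval overlaps no
    previously accepted one. Interval length counts query residues only, so
    query-gap columns contribute nothing.
    """
    if query_length < 1:
        raise ValueError("query_length must be >= 1")
    if not hsps:
        return 0.0
    ids = {(h.query_id, h.subject_id) for h in hsps}
    if len(ids) > 1:
        raise ValueError(f"HSPs must share one query-subject pair, got {ids}")
    ordered = sorted(hsps, key=lambda h: (-h.raw_score, -h.q_span, h.q_start))
    accepted: list[tuple[int, int]] = []
    covered = 0
    for h in ordered:
        lo, hi = h.q_interval
        if any(lo <= b and a <= hi for a, b in accepted):
            continue
        accepted.append((lo, hi))
        covered += hi - lo + 1
    return 100.0 * covered / query_length


def annotate_coverage(hitset: HitSet, query_length: int) -> None:
    """Fill the combined-coverage field of every hit in place."""
    for _, hit in hitset.all_hits():
        hit.coverage_pct = query_coverage(hit.hsps, query_length)


def filter_top_hits(hitset: HitSet, query_length: int, cfg: PipelineConfig) -> HitSet:
    """Keep the top_k subjects per organism, then apply the coverage and
    E-value filters (coverage >= min_coverage_pct, best E-value <= evalue_max)."""
    out = HitSet(query_id=hitset.query_id)
    for organism, hits in hitset.by_organism.items():
        kept: list[Hit] = []
        for hit in hits[: cfg.top_k]:
            if hit.coverage_pct is None:
                hit.coverage_pct = query_coverage(hit.hsps, query_length)
            if hit.coverage_pct >= cfg.min_coverage_pct and hit.best_evalue <= cfg.evalue_max:
                kept.append(hit)
        if kept:
            out.by_organism[organism] = kept
    return out


def reciprocal_confirm(
    query_id: str,
    candidate_id: str,
    db: ProteinDatabase,
    cfg: PipelineConfig,
) -> tuple[bool, float | None]:
    """Reverse-search a candidate against the full original database.

    Confirmed iff the original query appears among the reverse top_k
    coverage-passing hits within the query's own organism. Returns the
    confirmation flag and the reverse coverage of the query if hit.
    """
    if candidate_id not in db:
        raise KeyError(f"candidate {candidate_id} not in database")
    candidate = db[candidate_id]
    query_rec = db[query_id]
    rev = search_database(
        candidate.seq,
        db,
        cfg.scheme,
        evalue_max=cfg.evalue_max,
        per_subject_hsps=cfg.per_subject_hsps,
        query_id=candidate_id,
    )
    annotate_coverage(rev, len(candidate.seq))
    rev = filter_top_hits(rev, len(candidate.seq), cfg)
    for hit in rev.by_organism.get(query_rec.organism, []):
        if hit.subject_id == query_id:
            return True, hit.coverage_pct
    return False, None


def run_brb(
    seed_queries: Sequence[str],
    db: ProteinDatabase,
    cfg: PipelineConfig,
    log: list | None = None,
) -> OrthologTable:
    """Best-reciprocal-BLAST stage: forward search, top-k/coverage filter,
    reverse confirmation; one call per confirmed (organism, subject)."""
    table = OrthologTable()
    for query_id in seed_queries:
        if query_id not in db:
            raise KeyError(f"seed query {query_id} not in database")
        query = db[query_id]
        fwd = search_database(
            query.seq,
            db,
            cfg.scheme,
            evalue_max=cfg.evalue_max,
            per_subject_hsps=cfg.per_subject_hsps,
            query_id=query_id,
        )
        annotate_coverage(fwd, len(query.seq))
        fwd = filter_top_hits(fwd, len(query.seq), cfg)
        for organism in sorted(fwd.by_organism):
            for hit in fwd.by_organism[organism]:
                confirmed, rev_cov = reciprocal_confirm(query_id, hit.subject_id, db, cfg)
                if log is not None:
                    log.append(
                        {
                            "stage": "brb",
                            "query_id": query_id,
                            "subject_id": hit.subject_id,
                            "organism": organism,
                            "coverage_pct": hit.coverage_pct,
                            "evalue": hit.best_evalue,
                            "reverse_coverage_pct": rev_cov,
                            "decision": "accept" if confirmed else "reject",
                        }
                    )
                if confirmed:
                    table.add(
                        OrthologCall(
                            query_id=query_id,
                            subject_id=hit.subject_id,
                            organism=organism,
                            coverage_pct=hit.coverage_pct,
                            evidence_tier="reciprocal",
                            iteration_found=0,
                        )
                    )
    return table
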