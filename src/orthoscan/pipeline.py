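"""End-to-end orchestration of the orthology procedure.

Stage order: reciprocal-best-hit search, tree confirmation, iterative
profile expansion (with tree re-confirmation of additions), and a
structure-based screen as a last resort for organisms where sequence
methods found nothing. A (family, organism) pair found by an earlier stage
is never re-assigned by a later one. The run log records every threshold
decision so any accept/reject can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .db import ProteinDatabase
from .orthocall import OrthologCall, OrthologTable, PipelineConfig, run_brb
from .profilex import expand_iteratively, progressive_align, trim_columns
from .structhom import StructureModel, segment_domains, structural_ortholog_screen
from .treecheck import clade_confirm, neighbor_joining, protein_distance_matrix


@dataclass
class DistributionMatrix:
    """Presence/absence of each query family across organisms.

    Cell status: 'found' (at least one high-confidence call),
    'low_confidence' (only downgraded calls), or 'absent'. Counts are
    distinct subject ids; the incomplete flag marks cells whose accepted
    subjects are all much shorter than the family's median member.
    """

    status: pd.DataFrame  # rows: query families, cols: organisms
    counts: pd.DataFrame
    incomplete: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        cells = self.status.copy()
        for q in cells.index:
            for org in cells.columns:
                st = self.status.loc[q, org]
                if st == "absent":
                    cells.loc[q, org] = "absent:0"
                else:
                    star = "*" if self.incomplete.loc[q, org] else ""
                    cells.loc[q, org] = f"{st}:{self.counts.loc[q, org]}{star}"
        cells.to_csv(path, sep="\t", index_label="family")

    def plot(self, path: str | Path) -> None:
        """Grid rendering: filled = found, gray = low confidence, open = absent."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        nrow, ncol = self.status.shape
        fig, ax = plt.subplots(figsize=(0.4 * ncol + 2, 0.4 * nrow + 1.5))
        colors = {"found": "black", "low_confidence": "lightgray", "absent": "white"}
        for i, fam in enumerate(self.status.index):
            for j, org in enumerate(self.status.columns):
                st = self.status.loc[fam, org]
                ax.scatter(j, nrow - 1 - i, s=180, facecolor=colors[st],
                           edgecolor="black", zorder=3)
                n = self.counts.loc[fam, org]
                if n > 1:
                    ax.annotate(str(n), (j, nrow - 1 - i), ha="center",
                                va="center", fontsize=7, color="white")
        ax.set_xticks(range(ncol))
        ax.set_xticklabels(self.status.columns, rotation=90)
        ax.set_yticks(range(nrow))
        ax.set_yticklabels(list(self.status.index)[::-1])
        ax.set_xlim(-0.5, ncol - 0.5)
        ax.set_ylim(-0.5, nrow - 0.5)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def write_distribution_matrix(
    table: OrthologTable,
    organisms: list[str],
    db: ProteinDatabase,
    families: list[str] | None = None,
) -> DistributionMatrix:
    """Collapse an ortholog table into the per-(family, organism) grid."""
    known = set(organisms)
    for call in table:
        if call.organism not in known:
            raise ValueError(f"call references unknown organism: {call.organism}")
    if families is None:
        families = sorted({c.query_id for c in table})
    status = pd.DataFrame("absent", index=families, columns=organisms)
    counts = pd.DataFrame(0, index=families, columns=organisms)
    incomplete = pd.DataFrame(False, index=families, columns=organisms)
    for fam in families:
        calls = table.subjects_for(fam)
        if not calls:
            continue
        med = float(np.median([len(db[c.subject_id].seq) for c in calls]))
        for org in organisms:
            here = [c for c in calls if c.organism == org]
            if not here:
                continue
            counts.loc[fam, org] = len({c.subject_id for c in here})
            if any(c.confidence == "high" for c in here):
                status.loc[fam, org] = "found"
            else:
                status.loc[fam, org] = "low_confidence"
            if all(len(db[c.subject_id].seq) < 0.5 * med for c in here):
                incomplete.loc[fam, org] = True
    return DistributionMatrix(status=status, counts=counts, incomplete=incomplete)


def _tree_confirm_stage(
    table: OrthologTable,
    db: ProteinDatabase,
    cfg: PipelineConfig,
    query_id: str,
    candidate_tiers: tuple[str, ...],
    log: list,
) -> None:
    """Build the family tree and downgrade flagged candidates in place."""
    calls = table.subjects_for(query_id)
    member_ids = [c.subject_id for c in calls]
    confirmed = [c.subject_id for c in calls if c.evidence_tier == "reciprocal"]
    candidates = [c.subject_id for c in calls if c.evidence_tier in candidate_tiers]
    if not candidates:
        return
    if len(member_ids) < 4:
        for cand in candidates:
            log.append({"stage": "tree", "query_id": query_id, "subject_id": cand,
                        "decision": "pass", "reason": "too few members for a tree"})
        return
    msa = progressive_align([(m, db[m].seq) for m in member_ids], cfg.scheme)
    trimmed = trim_columns(msa, cfg.trim_max_gap_fraction)
    if trimmed.n_cols == 0:
        trimmed = msa
    dm = protein_distance_matrix(trimmed)
    tree = neighbor_joining(dm)
    for flag in clade_confirm(tree, confirmed, candidates):
        decision = "pass" if flag.status == "pass" else "downgrade"
        log.append({"stage": "tree", "query_id": query_id,
                    "subject_id": flag.candidate_id, "decision": decision,
                    "reason": flag.reason})
        if flag.status != "pass":
            table.set_confidence(query_id, flag.candidate_id, "low")


@dataclass
class PipelineResult:
    table: OrthologTable
    matrix: DistributionMatrix
    log: list[dict] = field(default_factory=list)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log)


def run_pipeline(
    cfg: PipelineConfig,
    db: ProteinDatabase,
    seed_queries: list[str],
    structures: dict[str, StructureModel] | None = None,
) -> PipelineResult:
    """Run BRB, tree confirmation, profile expansion, and (optionally) the
    structural screen; emit the ortholog table and distribution matrix.

    Fully deterministic: no stage draws random numbers. Structure-based
    calls are only attempted for organisms where sequence stages found
    nothing, and are recorded as low confidence.
    """
    log: list[dict] = []
    table = run_brb(seed_queries, db, cfg, log=log)
    table = expand_iteratively(table, db, cfg, log=log) if len(table) else table
    for query_id in seed_queries:
        _tree_confirm_stage(table, db, cfg, query_id, ("profile",), log)
    if structures:
        _structural_stage(table, db, cfg, seed_queries, structures, log)
    organisms = db.organisms
    matrix = write_distribution_matrix(table, organisms, db,
                                       families=list(seed_queries))
    return PipelineResult(table=table, matrix=matrix, log=log)


def _structural_stage(
    table: OrthologTable,
    db: ProteinDatabase,
    cfg: PipelineConfig,
    seed_queries: list[str],
    structures: dict[str, StructureModel],
    log: list,
) -> None:
    for query_id in seed_queries:
        if query_id not in structures:
            continue
        covered = {c.organism for c in table.subjects_for(query_id)}
        absent_orgs = [o for o in db.organisms if o not in covered]
        if not absent_orgs:
            continue
        qmodel = structures[query_id]
        domains = segment_domains(qmodel)
        if domains:
            dom = max(domains, key=lambda d: d.length)
            qdomain = qmodel.slice(dom.start, dom.end)
        else:
            qdomain = qmodel
        candidates = []
        for o in absent_orgs:
            for r in db.by_organism(o):
                if r.id not in structures:
                    continue
                cand = structures[r.id]
                if cand.model_id != r.id:
                    cand = StructureModel(r.id, cand.coords, cand.confidence,
                                          cand.sequence)
                candidates.append(cand)
        if not candidates:
            continue
        org_of = {r.id: r.organism for r in db}
        for res in structural_ortholog_screen(
            qdomain, candidates, accept_rmsd_max=cfg.accept_rmsd_max
        ):
            log.append({"stage": "structure", "query_id": query_id,
                        "subject_id": res.candidate_id,
                        "rmsd": res.rmsd, "decision": res.verdict,
                        "reason": res.reason})
            if res.verdict == "positive":
                if cfg.min_length_residues is not None and (
                    len(db[res.candidate_id].seq) < cfg.min_length_residues
                ):
                    continue
                table.add(
                    OrthologCall(
                        query_id=query_id,
                        subject_id=res.candidate_id,
                        organism=org_of[res.candidate_id],
                        coverage_pct=None,
                        evidence_tier="structural",
                        iteration_found=0,
                        confidence="low",
                        rmsd=res.rmsd,
                    )
                )
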