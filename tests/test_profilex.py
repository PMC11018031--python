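"""Progressive MSA, trimming, profiles, and the expansion loop."""

import numpy as np
import pytest

from orthoscan.db import ProteinDatabase, Record
from orthoscan.orthocall import OrthologCall, OrthologTable, PipelineConfig, run_brb
from orthoscan.profilex import (
    GAP,
    MSA,
    build_profile,
    expand_iteratively,
    member_self_scores,
    profile_search,
    progressive_align,
    trim_columns,
)
from orthoscan.scoring import AMINO_ACIDS, BLOSUM62
from orthoscan.synthgen import FamilySpec, SpeciesTree, simulate_family

from conftest import random_protein


class TestProgressiveAlign:
    def test_identical_pair_aligns_gap_free(self):
        msa = progressive_align([("a", "MKWLVDE"), ("b", "MKWLVDE")])
        assert msa.rows == ["MKWLVDE", "MKWLVDE"]

    def test_single_deletion_gives_one_gap_column(self):
        msa = progressive_align([("a", "MKLV"), ("b", "MKV")])
        assert msa.rows == ["MKLV", "MK-V"]

    def test_single_sequence_returned_as_one_row(self):
        msa = progressive_align([("a", "MKLV")])
        assert msa.ids == ["a"]
        assert msa.rows == ["MKLV"]

    def test_ungapping_reproduces_input_sequences(self):
        tree = SpeciesTree.from_newick(
            "((A:0.2,B:0.2):0.1,(C:0.3,D:0.1):0.1);"
        )
        fam = simulate_family(tree, FamilySpec(root_length=80, indel_rate=0.05, seed=3))
        seqs = sorted(fam.sequences.items())
        msa = progressive_align(seqs)
        for (sid, seq), row in zip(seqs, [msa.rows[msa.ids.index(s)] for s, _ in seqs]):
            assert row.replace(GAP, "") == seq

    def test_row_order_follows_input_order(self):
        seqs = [("z", "MKLVAD"), ("a", "MKLVAE"), ("m", "MKLIAD")]
        msa = progressive_align(seqs)
        assert msa.ids == ["z", "a", "m"]


class TestTrimColumns:
    def test_gap_fraction_thresholds(self):
        msa = MSA(["a", "b", "c", "d"], ["MK-LV", "MKALV", "MK-LV", "MKA-V"])
        # column 3: 2/4 gaps (0.50) removed at 0.25; column 4: 1/4 (0.25) kept
        strict = trim_columns(msa, 0.25)
        assert strict.rows == ["MKLV", "MKLV", "MKLV", "MK-V"]
        relaxed = trim_columns(msa, 0.75)
        assert relaxed.rows == msa.rows

    def test_idempotent(self):
        msa = MSA(["a", "b", "c", "d"], ["MK-LV", "MKALV", "MK-LV", "MKA-V"])
        once = trim_columns(msa, 0.25)
        twice = trim_columns(once, 0.25)
        assert once.rows == twice.rows

    def test_gap_free_msa_unchanged(self):
        msa = MSA(["a", "b"], ["MKLV", "MKIV"])
        for thr in (0.0, 0.25, 1.0):
            assert trim_columns(msa, thr).rows == msa.rows

    def test_retained_columns_all_pass_threshold(self):
        msa = MSA(["a", "b", "c", "d"], ["M--LV", "MKALV", "M--LV", "MKA-V"])
        out = trim_columns(msa, 0.25)
        assert np.all(out.gap_fractions() <= 0.25)

    def test_empty_msa_rejected(self):
        with pytest.raises(ValueError):
            trim_columns(MSA([], []), 0.25)


class TestBuildProfile:
    def test_large_pseudocount_approaches_substitution_row(self):
        # single-residue column, pseudocount-dominated: the log-odds column
        # converges to the BLOSUM62 row of that residue (half-bit units)
        for aa in "WAL":
            prof = build_profile(MSA(["x"], [aa]), pseudocount=1e6)
            row = BLOSUM62[AMINO_ACIDS.index(aa), :20]
            # 0.5 bits = 1 half-bit tolerance per column entry
            assert np.all(np.abs(prof.scores[0] - row) <= 1.0)

    def test_conserved_column_dominated_by_observed_residue(self):
        msa = MSA([f"s{i}" for i in range(10)], ["W"] * 10)
        prof = build_profile(msa, pseudocount=1e-6)
        assert prof.scores[0].argmax() == AMINO_ACIDS.index("W")

    def test_deterministic(self):
        msa = MSA(["a", "b"], ["MKLV", "MKIV"])
        p1 = build_profile(msa)
        p2 = build_profile(msa)
        assert np.array_equal(p1.scores, p2.scores)

    def test_occupancy_records_gap_fraction(self):
        msa = MSA(["a", "b", "c", "d"], ["MK-LV", "MKALV", "MK-LV", "MKA-V"])
        prof = build_profile(msa)
        assert prof.occupancy[2] == pytest.approx(0.5)
        assert prof.occupancy[0] == pytest.approx(1.0)

    def test_profile_tsv_round_trip_columns(self, tmp_path):
        msa = MSA(["a", "b"], ["MKLV", "MKIV"])
        prof = build_profile(msa)
        path = tmp_path / "prof.tsv"
        prof.to_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header[2:] == list(AMINO_ACIDS)


class TestProfileSearch:
    def _family_db(self, rng):
        tree = SpeciesTree.from_newick(
            "((A:0.15,B:0.15):0.1,(C:0.15,D:0.15):0.1);"
        )
        fam = simulate_family(tree, FamilySpec(root_length=120, seed=8))
        records = [
            Record(id=f"{org}|fam", organism=org, seq=seq)
            for org, seq in sorted(fam.sequences.items())
        ]
        for org in "ABCD":
            for k in range(5):
                records.append(
                    Record(id=f"{org}|d{k}", organism=org,
                           seq=random_protein(rng, 120))
                )
        return ProteinDatabase(records)

    def test_family_member_outscores_decoys(self, rng, cfg):
        db = self._family_db(rng)
        members = ["A|fam", "B|fam", "C|fam"]
        msa = progressive_align([(m, db[m].seq) for m in members])
        prof = build_profile(msa, source_msa_id="fam")
        hits = profile_search(prof, db, cfg)
        d_hits = hits.by_organism["D"]
        assert d_hits[0].subject_id == "D|fam"

    def test_member_self_scores_exceed_decoy_scores(self, rng, cfg):
        db = self._family_db(rng)
        members = ["A|fam", "B|fam", "C|fam"]
        msa = progressive_align([(m, db[m].seq) for m in members])
        prof = build_profile(msa, source_msa_id="fam")
        self_scores = member_self_scores(prof, db, cfg)
        hits = profile_search(prof, db, cfg)
        decoy_scores = [
            h.hsps[0].raw_score
            for org, hit_list in hits.by_organism.items()
            for h in hit_list
            if "|d" in h.subject_id
        ]
        assert min(self_scores.values()) > max(decoy_scores)


def chain_family_db():
    """A divergence chain: D is too far from A for direct reciprocal search
    but reachable once the profile contains A+B+C."""
    tree = SpeciesTree.from_newick(
        "(((A:0.05,B:0.45):0.55,C:0.55):0.6,D:0.55);"
    )
    fam = simulate_family(tree, FamilySpec(root_length=150, seed=21))
    records = [
        Record(id=f"{org}|fam", organism=org, seq=seq)
        for org, seq in sorted(fam.sequences.items())
    ]
    rng = np.random.default_rng(99)
    for org in "ABCD":
        for k in range(3):
            records.append(
                Record(id=f"{org}|d{k}", organism=org, seq=random_protein(rng, 150))
            )
    return ProteinDatabase(records)


class TestExpandIteratively:
    def test_fixed_point_when_brb_found_everything(self, duplicated_db, cfg):
        table = run_brb(["orgA|p0"], duplicated_db, cfg)
        out = expand_iteratively(table, duplicated_db, cfg)
        assert {(c.query_id, c.subject_id) for c in out} == {
            (c.query_id, c.subject_id) for c in table
        }

    def test_membership_monotone_and_iterations_recorded(self, cfg):
        db = chain_family_db()
        brb = run_brb(["A|fam"], db, cfg)
        out = expand_iteratively(brb, db, cfg)
        brb_keys = {(c.query_id, c.subject_id) for c in brb}
        out_keys = {(c.query_id, c.subject_id) for c in out}
        assert brb_keys <= out_keys
        for c in out:
            if c.evidence_tier == "profile":
                assert c.iteration_found >= 1

    def test_expansion_recovers_chain_member_missed_by_brb(self, cfg):
        db = chain_family_db()
        brb = run_brb(["A|fam"], db, cfg)
        brb_subjects = {c.subject_id for c in brb}
        assert "D|fam" not in brb_subjects  # BRB alone misses the far leaf
        out = expand_iteratively(brb, db, cfg)
        assert "D|fam" in {c.subject_id for c in out}

    def test_output_is_a_fixed_point(self, cfg):
        db = chain_family_db()
        out = expand_iteratively(run_brb(["A|fam"], db, cfg), db, cfg)
        again = expand_iteratively(out, db, cfg)
        assert {(c.query_id, c.subject_id) for c in again} == {
            (c.query_id, c.subject_id) for c in out
        }

    def test_empty_confirmed_table_rejected(self, cfg):
        with pytest.raises(ValueError):
            expand_iteratively(OrthologTable(), ProteinDatabase([]), cfg)
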