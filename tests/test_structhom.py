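"""Kabsch superposition, domain segmentation, RMSD screens, filters."""

import numpy as np
import pytest

from orthoscan.structhom import (
    AnnotatedCandidate,
    StructureModel,
    cross_model_consensus,
    filter_by_topology_and_length,
    kabsch_superpose,
    read_structure,
    segment_domains,
    structural_ortholog_screen,
    write_structure,
)
from orthoscan.synthgen import (
    self_avoiding_chain,
    simulate_structure_pair,
    structure_pair_with_rmsd,
)

from _oracles import min_rmsd_over_rotations


class TestKabsch:
    def test_identity_on_equal_inputs(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(20, 3))
        R, t, rmsd = kabsch_superpose(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3))
        assert np.allclose(t, 0, atol=1e-12)

    def test_rigid_motion_recovered_and_rmsd_zero(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(30, 3))
        theta = 0.7
        Rz = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        B = A @ Rz.T + np.array([5.0, -2.0, 3.0])
        R, t, rmsd = kabsch_superpose(A, B)
        assert rmsd < 1e-9
        assert np.allclose(R @ Rz, np.eye(3), atol=1e-9)

    def test_agrees_with_rotation_space_minimizer_on_toy(self):
        A = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 2.0]])
        B = A.copy()
        B[2, 2] += 1.0  # 1 A displacement of one atom
        _, _, rmsd = kabsch_superpose(A, B)
        assert rmsd == pytest.approx(min_rmsd_over_rotations(A, B), abs=1e-6)

    def test_symmetry_and_rigid_invariance(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(25, 3)) * 5
        B = A + rng.normal(size=(25, 3))
        _, _, r_ab = kabsch_superpose(A, B)
        _, _, r_ba = kabsch_superpose(B, A)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        Q, _, _ = np.linalg.svd(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        _, _, r_rot = kabsch_superpose(A, B @ Q.T + 7.0)
        assert r_rot == pytest.approx(r_ab, abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_correspondence_subset(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(10, 3)) * 4
        B = np.vstack([A[5:], A[:5]])  # shuffled halves
        pairs = [(i, (i + 5) % 10) for i in range(10)]
        _, _, rmsd = kabsch_superpose(A, B, pairs)
        assert rmsd < 1e-9


class TestSegmentDomains:
    def _model(self, conf):
        conf = np.asarray(conf, float)
        coords = self_avoiding_chain(len(conf), np.random.default_rng(0))
        return StructureModel("m", coords, conf, "A" * len(conf))

    def test_uniform_high_confidence_single_domain(self):
        model = self._model(np.full(120, 90.0))
        [dom] = segment_domains(model)
        assert (dom.start, dom.end) == (1, 120)
        assert dom.mean_confidence == pytest.approx(90.0)

    def test_two_domains_separated_by_disordered_stretch(self):
        conf = np.concatenate(
            [np.full(120, 90.0), np.full(40, 30.0), np.full(140, 90.0)]
        )
        doms = segment_domains(self._model(conf))
        assert [(d.start, d.end) for d in doms] == [(1, 120), (161, 300)]

    def test_uniformly_low_confidence_yields_nothing(self):
        assert segment_domains(self._model(np.full(100, 40.0))) == []

    def test_short_runs_dropped_and_close_runs_merged(self):
        conf = np.concatenate(
            [np.full(60, 90.0), np.full(5, 30.0), np.full(60, 90.0),
             np.full(60, 30.0), np.full(20, 90.0)]
        )
        doms = segment_domains(self._model(conf))
        # gap of 5 < merge_gap merges the first two runs; trailing 20 < min_len
        assert [(d.start, d.end) for d in doms] == [(1, 125)]

    def test_intervals_disjoint_and_sorted(self):
        rng = np.random.default_rng(9)
        conf = rng.uniform(20, 100, size=400)
        doms = segment_domains(self._model(conf))
        for d1, d2 in zip(doms, doms[1:]):
            assert d1.end < d2.start


class TestCrossModelConsensus:
    def test_agreement_just_below_five_angstrom(self):
        A, B = structure_pair_with_rmsd(80, 4.9, seed=1)
        ok, rep, rmsds = cross_model_consensus([A, B])
        assert ok
        assert rep is not None

    def test_disagreement_at_exactly_five_angstrom(self):
        A, B = structure_pair_with_rmsd(80, 5.0, seed=2)
        ok, rep, _ = cross_model_consensus([A, B])
        assert not ok
        assert rep is None

    def test_identical_models_pick_lowest_id(self):
        A, _, _ = simulate_structure_pair(50, 0.0, seed=3)
        m1 = StructureModel("m2", A.coords, A.confidence, A.sequence)
        m2 = StructureModel("m1", A.coords.copy(), A.confidence.copy(), A.sequence)
        ok, rep, _ = cross_model_consensus([m1, m2])
        assert ok
        assert rep.model_id == "m1"

    def test_mismatched_lengths_rejected(self):
        A, _, _ = simulate_structure_pair(50, 0.0, seed=4)
        B, _, _ = simulate_structure_pair(40, 0.0, seed=5)
        with pytest.raises(ValueError):
            cross_model_consensus([A, B])


class TestStructuralScreen:
    def test_rigid_copy_is_positive_with_near_zero_rmsd(self):
        A, B, _ = simulate_structure_pair(100, 0.0, seed=6)
        [res] = structural_ortholog_screen(A, [B])
        assert res.verdict == "positive"
        assert res.rmsd < 1e-6

    def test_acceptance_boundary_is_strict_at_three_angstrom(self):
        A29, B29 = structure_pair_with_rmsd(100, 2.9, seed=7)
        A30, B30 = structure_pair_with_rmsd(100, 3.0, seed=8)
        A31, B31 = structure_pair_with_rmsd(100, 3.1, seed=9)
        assert structural_ortholog_screen(A29, [B29])[0].verdict == "positive"
        assert structural_ortholog_screen(A30, [B30])[0].verdict == "negative"
        assert structural_ortholog_screen(A31, [B31])[0].verdict == "negative"

    def test_unrelated_chain_is_negative(self):
        A, _, _ = simulate_structure_pair(100, 0.0, seed=10)
        C, _, _ = simulate_structure_pair(100, 0.0, seed=11)
        [res] = structural_ortholog_screen(A, [C])
        assert res.verdict == "negative"

    def test_insufficient_correspondence_reported(self):
        A, _, _ = simulate_structure_pair(100, 0.0, seed=12)
        short = A.slice(1, 20, model_id="frag")
        # reversed sequence: global alignment finds few consistent pairs
        rev = StructureModel(
            "rev", short.coords[::-1].copy(), short.confidence.copy(),
            short.sequence[::-1],
        )
        results = structural_ortholog_screen(A, [rev])
        assert results[0].verdict == "negative"


class TestTopologyAndLengthFilter:
    CANDS = [
        AnnotatedCandidate("good", ("SP", "TM", "TM", "cytB561"), 1200),
        AnnotatedCandidate("short", ("TM", "TM", "cytB561"), 999),
        AnnotatedCandidate("boundary", ("TM", "TM", "cytB561"), 1000),
        AnnotatedCandidate("wrong_order", ("cytB561", "TM", "TM"), 1500),
    ]

    def test_subsequence_match_with_extra_domains(self):
        kept = filter_by_topology_and_length(
            self.CANDS, ["TM", "TM", "cytB561"], min_length=None
        )
        assert [c.candidate_id for c in kept] == ["good", "short", "boundary"]

    def test_length_boundary_excludes_999_keeps_1000(self):
        kept = filter_by_topology_and_length(
            self.CANDS, ["TM", "TM", "cytB561"], min_length=1000
        )
        assert [c.candidate_id for c in kept] == ["good", "boundary"]

    def test_empty_topology_keeps_everything_subject_to_length(self):
        kept = filter_by_topology_and_length(self.CANDS, [], min_length=1000)
        assert [c.candidate_id for c in kept] == ["good", "boundary", "wrong_order"]


class TestPdbIo:
    def test_round_trip_preserves_coordinates_and_confidence(self, tmp_path):
        A, _, _ = simulate_structure_pair(30, 0.0, seed=13)
        path = tmp_path / "a.pdb"
        write_structure(A, path)
        back = read_structure(path, model_id="A")
        assert back.sequence == A.sequence
        assert np.allclose(back.coords, A.coords, atol=1e-3)  # PDB precision
        assert np.allclose(back.confidence, A.confidence, atol=1e-2)
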