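"""Distances, neighbor joining, and clade-based confirmation."""

import dendropy
import numpy as np
import pytest

from orthoscan.profilex import MSA
from orthoscan.treecheck import (
    DISTANCE_CAP,
    CladeFlag,
    DistanceMatrix,
    clade_confirm,
    kimura_protein_distance,
    neighbor_joining,
    protein_distance_matrix,
    tree_to_newick,
)

from _oracles import best_ls_topology, tree_splits


class TestKimuraDistance:
    def test_identical_sequences_distance_zero(self):
        assert kimura_protein_distance(0.0) == 0.0

    def test_closed_form_at_p_01(self):
        assert kimura_protein_distance(0.1) == pytest.approx(0.10758, abs=1e-4)

    def test_cap_beyond_domain_edge(self):
        # 1 - p - 0.2 p^2 = 0 at p ~ 0.8541
        assert kimura_protein_distance(0.8541) == DISTANCE_CAP
        assert kimura_protein_distance(0.99) == DISTANCE_CAP
        assert kimura_protein_distance(0.80) < DISTANCE_CAP


class TestProteinDistanceMatrix:
    def test_identical_rows_give_zero(self):
        msa = MSA(["a", "b", "c"], ["MKLV", "MKLV", "MKLV"])
        dm = protein_distance_matrix(msa)
        assert np.allclose(dm.matrix, 0)

    def test_distances_use_mutually_ungapped_columns(self):
        msa = MSA(["a", "b", "c"], ["MKLV", "MK-V", "MKLV"])
        dm = protein_distance_matrix(msa)
        assert dm.matrix[0, 1] == 0.0  # 3 shared columns, all identical

    def test_no_shared_columns_rejected(self):
        msa = MSA(["a", "b", "c"], ["MK--", "--LV", "MKLV"])
        with pytest.raises(ValueError, match="mutually ungapped"):
            protein_distance_matrix(msa)

    def test_fewer_than_three_sequences_rejected(self):
        with pytest.raises(ValueError):
            protein_distance_matrix(MSA(["a", "b"], ["MK", "MK"]))


def random_additive_matrix(n_taxa, seed):
    """Patristic distances of a random binary tree with known branch lengths."""
    rng = np.random.default_rng(seed)
    from orthoscan.synthgen import random_species_tree

    labels = [chr(ord("A") + i) for i in range(n_taxa)]
    st = random_species_tree(labels, rng, max_branch=2.0, min_branch=0.1)
    pdm = st.tree.phylogenetic_distance_matrix()
    D = np.zeros((n_taxa, n_taxa))
    taxa = {t.label: t for t in st.tree.taxon_namespace}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[i, j] = D[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
    return labels, D, st


class TestNeighborJoining:
    def test_additive_four_taxon_exact_recovery(self):
        # ((A:1,B:2):1,(C:3,D:4)) -> pairwise distances below
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(labels, D))
        splits = tree_splits(tree, labels)
        assert splits == frozenset([frozenset(["A", "B"])])
        # branch lengths: terminal edges 1,2,3,4 and internal 1
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        for lbl, expect in zip("ABCD", (1, 2, 3, 4)):
            assert lengths[lbl] == pytest.approx(expect, abs=1e-9)

    def test_matches_least_squares_oracle_on_random_additive(self):
        for seed in range(6):
            for n in (4, 5):
                labels, D, _ = random_additive_matrix(n, 100 + seed)
                tree = neighbor_joining(DistanceMatrix(labels, D))
                got = tree_splits(tree, labels)
                oracle_splits, rss = best_ls_topology(labels, D)
                norm = frozenset(
                    min(s, frozenset(labels) - s, key=lambda x: (len(x), sorted(x)))
                    for s in oracle_splits
                )
                assert got == norm
                assert rss < 1e-12

    def test_exact_on_larger_random_additive_trees(self):
        for seed in range(5):
            n = 5 + seed  # 5..9 taxa
            labels, D, st = random_additive_matrix(n, 7 + seed)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            # recovered tree's patristic distances reproduce the input
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        assert pdm.patristic_distance(
                            taxa[a], taxa[b]
                        ) == pytest.approx(D[i, j], abs=1e-9)

    def test_star_matrix_gives_zero_internal_branches(self):
        labels = ["A", "B", "C", "D"]
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        tree = neighbor_joining(DistanceMatrix(labels, D))
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not None and not edge.head_node.is_leaf():
                if edge.length is not None:
                    assert abs(edge.length) < 1e-9

    def test_label_permutation_invariance(self):
        labels, D, _ = random_additive_matrix(5, 55)
        t1 = neighbor_joining(DistanceMatrix(labels, D))
        perm = [3, 1, 4, 0, 2]
        labels2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        t2 = neighbor_joining(DistanceMatrix(labels2, D2))
        assert tree_splits(t1, labels) == tree_splits(t2, labels)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [9, 2, 1, 0]], float)
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B", "C", "D"], D)

    def test_newick_output_parses(self):
        labels, D, _ = random_additive_matrix(5, 3)
        tree = neighbor_joining(DistanceMatrix(labels, D))
        nwk = tree_to_newick(tree)
        reparsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(lf.taxon.label for lf in reparsed.leaf_node_iter()) == sorted(labels)


def family_tree_with_outlier():
    """NJ tree from additive distances: a tight family containing the
    candidate, plus one decoy on a huge terminal branch."""
    from orthoscan.synthgen import SpeciesTree

    st = SpeciesTree.from_newick(
        "((((m1:0.1,cand:0.12):0.05,m2:0.2):0.1,(m3:0.15,m4:0.15):0.1):0.1,"
        "decoy:3.0);"
    )
    labels = ["m1", "m2", "m3", "m4", "cand", "decoy"]
    pdm = st.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in st.tree.taxon_namespace}
    D = np.zeros((6, 6))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[i, j] = D[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
    return neighbor_joining(DistanceMatrix(labels, D))


class TestCladeConfirm:
    def test_candidate_inside_family_clade_passes(self):
        tree = family_tree_with_outlier()
        flags = clade_confirm(tree, ["m1", "m2", "m3", "m4"], ["cand"])
        assert flags == [
            CladeFlag("cand", "pass", "inside clade, branch length typical")
        ]

    def test_long_branch_decoy_flagged(self):
        tree = family_tree_with_outlier()
        [flag] = clade_confirm(tree, ["m1", "m2", "m3", "m4"], ["decoy"])
        assert flag.status == "flagged"

    def test_candidate_identical_to_member_passes(self):
        labels = ["m1", "m2", "m3", "cand"]
        D = np.array(
            [[0, 0.4, 0.4, 0.0], [0.4, 0, 0.4, 0.4],
             [0.4, 0.4, 0, 0.4], [0.0, 0.4, 0.4, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(labels, D))
        [flag] = clade_confirm(tree, ["m1", "m2", "m3"], ["cand"])
        assert flag.status == "pass"

    def test_too_few_confirmed_members_unevaluable(self):
        tree = family_tree_with_outlier()
        flags = clade_confirm(tree, ["m1"], ["cand", "decoy"])
        assert all(f.status == "unevaluable" for f in flags)

    def test_confirmation_never_removes_candidates(self):
        tree = family_tree_with_outlier()
        flags = clade_confirm(tree, ["m1", "m2", "m3", "m4"], ["cand", "decoy"])
        assert [f.candidate_id for f in flags] == ["cand", "decoy"]
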