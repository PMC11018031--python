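"""Distance-based confirmation trees.

Kimura-corrected protein distances from a trimmed MSA, canonical
Saitou-Nei neighbor joining with deterministic tie-breaking, and an
explicit clade-membership rule that downgrades (never removes) ortholog
calls that sit outside the family clade or on conspicuously long branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .profilex import GAP, MSA

#: Distances beyond the domain of the Kimura correction are capped here.
DISTANCE_CAP = 5.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise ValueError("entries must be finite and non-negative")


def kimura_protein_distance(p: float) -> float:
    """Kimura's empirical correction d = -ln(1 - p - 0.2 p^2), capped at
    DISTANCE_CAP where the argument leaves the correction's domain."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= np.exp(-DISTANCE_CAP):
        return DISTANCE_CAP
    return float(-np.log(arg))


def protein_distance_matrix(msa: MSA) -> DistanceMatrix:
    """Pairwise Kimura-corrected p-distances over mutually ungapped columns."""
    if msa.n_seqs < 3:
        raise ValueError("need at least 3 sequences")
    n = msa.n_seqs
    arr = np.array([list(r) for r in msa.rows])
    ungapped = arr != GAP
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no mutually ungapped columns between {msa.ids[i]} and {msa.ids[j]}"
                )
            p = float((arr[i, both] != arr[j, both]).mean())
            D[i, j] = D[j, i] = kimura_protein_distance(p)
    return DistanceMatrix(list(msa.ids), D)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical Saitou-Nei NJ with deterministic tie-breaking.

    Ties in the Q criterion are resolved toward the pair whose (smallest
    cluster leaf label, largest) is lexicographically least. On an additive
    matrix the true topology and exact branch lengths are recovered.
    """
    n = len(dm.labels)
    if n < 4:
        raise ValueError("need at least 4 labels")
    D = dm.matrix.copy()
    # each active cluster: (tie-break label, newick fragment)
    items: list[tuple[str, str]] = [(lbl, f"'{lbl}'") for lbl in dm.labels]
    active = list(range(n))
    while len(active) > 2:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                lab = tuple(sorted((items[i][0], items[j][0])))
                key = (q, lab)
                if best_q is None or key < best_q:
                    best_q = key
                    best = (i, j)
        i, j = best
        dij = D[i, j]
        bi = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        bj = dij - bi
        new_frag = f"({items[i][1]}:{float(bi)!r},{items[j][1]}:{float(bj)!r})"
        new_label = min(items[i][0], items[j][0])
        # distances to the new node
        newD = np.zeros(len(items) + 1)
        for k in active:
            if k in (i, j):
                continue
            newD[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.vstack([D, newD[: D.shape[1]][np.newaxis, :]])
        D = np.hstack([D, np.append(newD[: D.shape[0] - 1], 0.0)[:, np.newaxis]])
        items.append((new_label, new_frag))
        active = [k for k in active if k not in (i, j)] + [len(items) - 1]
    i, j = active
    newick = f"({items[i][1]}:{float(D[i, j])!r},{items[j][1]}:0.0);"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


@dataclass(frozen=True)
class CladeFlag:
    candidate_id: str
    status: str  # pass | flagged | unevaluable
    reason: str


def clade_confirm(
    tree: dendropy.Tree,
    confirmed_ids: list[str],
    candidate_ids: list[str],
    branch_factor: float = 3.0,
) -> list[CladeFlag]:
    """Tree-based confirmation of candidate orthologs.

    The tree is midpoint-rooted; a candidate passes iff it lies inside the
    smallest clade containing all confirmed members AND its terminal branch
    is at most branch_factor times the median terminal branch of confirmed
    members. Failures are flagged, never removed.
    """
    if len(confirmed_ids) < 2:
        return [
            CladeFlag(c, "unevaluable", "fewer than 2 confirmed members")
            for c in candidate_ids
        ]
    original = tree
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint(update_bipartitions=True)
    if sum(1 for _ in tree.leaf_node_iter()) != n_leaves:
        # midpoint fell exactly on a node and the rerooted tree lost a
        # leaf (degenerate zero-length case); keep the original rooting
        tree = original.clone(depth=1)
    tree.is_rooted = True
    leaf = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = [x for x in list(confirmed_ids) + list(candidate_ids) if x not in leaf]
    if missing:
        raise KeyError(f"ids not in tree: {missing}")
    mrca = tree.mrca(taxa=[leaf[c].taxon for c in confirmed_ids])
    clade_leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
    term = [max(leaf[c].edge.length or 0.0, 0.0) for c in confirmed_ids]
    cutoff = branch_factor * float(np.median(term))
    out = []
    for cand in candidate_ids:
        if cand not in clade_leaves:
            out.append(CladeFlag(cand, "flagged", "outside the confirmed clade"))
            continue
        blen = max(leaf[cand].edge.length or 0.0, 0.0)
        if blen > cutoff:
            out.append(
                CladeFlag(
                    cand, "flagged",
                    f"terminal branch {blen:.3f} > {branch_factor:g}x median {cutoff / branch_factor:.3f}",
                )
            )
        else:
            out.append(CladeFlag(cand, "pass", "inside clade, branch length typical"))
    return out


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, real_value_format_specifier=".6f"
    ).strip()
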