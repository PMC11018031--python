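"""Independent oracles used to cross-check the main implementations.

These deliberately avoid the algorithms they verify: the local-alignment
oracle enumerates gap placements directly instead of using the affine
E/F recurrences; the tree oracle scores every unrooted topology by
least-squares; the superposition oracle minimizes over rotation space
numerically.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from orthoscan.scoring import DEFAULT_SCHEME, encode


def brute_local_score(query: str, subject: str, scheme=DEFAULT_SCHEME) -> int:
    """Best local alignment score by direct gap-length enumeration.

    H[i][j] considers, besides the diagonal, every gap length k charged
    open + k*extend in one step — O(n*m*(n+m)), no affine state matrices.
    """
    q = encode(query)
    s = encode(subject)
    sub = scheme.substitution_matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    n, m = len(q), len(s)
    H = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = 0
            d = H[i - 1][j - 1] + sub[q[i - 1]][s[j - 1]]
            if d > best:
                best = d
            for k in range(1, j + 1):
                v = H[i][j - k] - (go + ge * k)
                if v > best:
                    best = v
            for k in range(1, i + 1):
                v = H[i - k][j] - (go + ge * k)
                if v > best:
                    best = v
            H[i][j] = best
    return int(H.max())


def _unrooted_topologies(labels: list[str]):
    """All unrooted binary topologies as sets of splits (frozenset of the
    smaller side), built by stepwise leaf addition."""
    if len(labels) == 4:
        a, b, c, d = labels
        yield from (
            frozenset([frozenset([a, b])]),
            frozenset([frozenset([a, c])]),
            frozenset([frozenset([a, d])]),
        )
        return
    if len(labels) == 5:
        # 15 topologies: every pair of compatible non-trivial splits
        pairs = list(itertools.combinations(labels, 2))
        tops = set()
        for p1 in pairs:
            for p2 in pairs:
                s1, s2 = frozenset(p1), frozenset(p2)
                if s1 == s2 or s1 & s2:
                    continue
                tops.add(frozenset([s1, s2]))
        yield from sorted(tops, key=lambda t: sorted(map(sorted, t)))
        return
    raise ValueError("oracle supports 4 or 5 taxa")


def _edges_for_topology(labels, splits):
    """Edge list as leaf-side bipartitions (terminal + internal edges)."""
    full = frozenset(labels)
    edges = [frozenset([x]) for x in labels]
    edges.extend(splits)
    return edges, full


def ls_fit_topology(labels: list[str], D: np.ndarray, splits) -> float:
    """Least-squares branch-length fit of one topology to a distance
    matrix; returns the residual sum of squares."""
    edges, full = _edges_for_topology(labels, splits)
    idx = {lbl: i for i, lbl in enumerate(labels)}
    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        y[r] = D[idx[a], idx[b]]
        for e, side in enumerate(edges):
            # edge is on the a-b path iff the split separates a from b
            if (a in side) != (b in side):
                A[r, e] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


def best_ls_topology(labels: list[str], D: np.ndarray):
    """Topology (set of splits) with the smallest least-squares residual."""
    best = None
    for splits in _unrooted_topologies(labels):
        rss = ls_fit_topology(labels, D, splits)
        if best is None or rss < best[0]:
            best = (rss, splits)
    return best[1], best[0]


def tree_splits(tree, labels) -> frozenset:
    """Non-trivial splits of a dendropy tree, as frozensets of the side
    containing the first label's complement-normalised form."""
    full = frozenset(labels)
    out = set()
    tree2 = tree.clone(depth=1)
    tree2.encode_bipartitions()
    for edge in tree2.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.is_leaf():
            continue
        side = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        if 1 < len(side) < len(full) - 1:
            out.add(min(side, full - side, key=lambda s: (len(s), sorted(s))))
    return frozenset(out)


def min_rmsd_over_rotations(A: np.ndarray, B: np.ndarray) -> float:
    """RMSD minimized numerically over rotation vectors and translations."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        d = Bc @ R.T - Ac
        return (d**2).sum(axis=1).mean()

    best = np.inf
    for x0 in ([0.0, 0, 0], [np.pi, 0, 0], [0, np.pi, 0], [0, 0, np.pi],
               [1.0, 1.0, 1.0], [-1.0, 2.0, 0.5]):
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 20000})
        best = min(best, res.fun)
    return float(np.sqrt(best))
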