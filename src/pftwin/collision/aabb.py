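"""Axis-aligned bounding-box tree over triangle meshes.

Built by recursive median split of the dominant box axis; every leaf
encloses exactly one triangle.  Queries prune whole subtrees whose box
misses the probe, reducing candidate search from O(N) per probe toward
O(log N).
"""

from __future__ import annotations

from typing import List

import numpy as np

from ..errors import MeshError
from ..geometry import TriMesh

__all__ = ["AABBTree", "build_aabb_tree", "query_candidates"]


class AABBTree:
    """Flat-array AABB tree.  Node 0 is the root; leaves carry one triangle."""

    def __init__(self, lower, upper, left, right, tri, tri_lower, tri_upper):
        self.lower = lower          # (nodes, 3)
        self.upper = upper
        self.left = left            # child index or -1 at leaves
        self.right = right
        self.tri = tri              # triangle id at leaves, -1 internal
        self.tri_lower = tri_lower  # per-triangle boxes (n_tri, 3)
        self.tri_upper = tri_upper

    @property
    def n_nodes(self) -> int:
        return len(self.lower)

    @property
    def n_triangles(self) -> int:
        return len(self.tri_lower)

    def depth(self) -> int:
        depth = np.zeros(self.n_nodes, int)
        best = 0
        stack = [0]
        while stack:
            i = stack.pop()
            if self.left[i] < 0:
                best = max(best, depth[i])
                continue
            for c in (self.left[i], self.right[i]):
                depth[c] = depth[i] + 1
                stack.append(c)
        return int(best)

    def leaf_for_triangle(self) -> np.ndarray:
        """triangle id -> leaf node index."""
        out = np.full(self.n_triangles, -1, int)
        leaves = np.nonzero(self.left < 0)[0]
        out[self.tri[leaves]] = leaves
        return out


def build_aabb_tree(mesh: TriMesh) -> AABBTree:
    """Build the tree for a mesh (recursive median split, one-triangle leaves)."""
    if mesh.n_faces == 0:
        raise MeshError("cannot build an AABB tree over an empty mesh")
    tri = mesh.triangles
    tlo = tri.min(axis=1)
    thi = tri.max(axis=1)
    cent = 0.5 * (tlo + thi)

    lower: List[np.ndarray] = []
    upper: List[np.ndarray] = []
    left: List[int] = []
    right: List[int] = []
    tri_id: List[int] = []

    def build(ids: np.ndarray) -> int:
        node = len(lower)
        lower.append(tlo[ids].min(axis=0))
        upper.append(thi[ids].max(axis=0))
        left.append(-1)
        right.append(-1)
        tri_id.append(-1)
        if len(ids) == 1:
            tri_id[node] = int(ids[0])
            return node
        axis = int(np.argmax(upper[node] - lower[node]))
        order = ids[np.argsort(cent[ids, axis], kind="stable")]
        half = len(order) // 2
        left[node] = build(order[:half])
        right[node] = build(order[half:])
        return node

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        build(np.arange(mesh.n_faces))
    finally:
        sys.setrecursionlimit(old)
    return AABBTree(np.asarray(lower), np.asarray(upper),
                    np.asarray(left), np.asarray(right), np.asarray(tri_id),
                    tlo, thi)


def query_candidates(tree: AABBTree, box_lower, box_upper) -> np.ndarray:
    """Triangle ids whose leaf boxes intersect the probe box (superset of all
    actually intersecting triangles; pruned subtrees cannot intersect)."""
    lo = np.asarray(box_lower, float)
    hi = np.asarray(box_upper, float)
    front = np.zeros(1, np.int64)
    out: List[np.ndarray] = []
    while len(front):
        hit = np.all((tree.upper[front] >= lo) & (tree.lower[front] <= hi), axis=1)
        front = front[hit]
        if not len(front):
            break
        leaf = tree.left[front] < 0
        if np.any(leaf):
            out.append(tree.tri[front[leaf]])
        front = front[~leaf]
        front = np.concatenate([tree.left[front], tree.right[front]])
    if not out:
        return np.empty(0, np.int64)
    return np.sort(np.concatenate(out))


def _transform_box(lo, hi, R, t):
    """AABB of a rotated box: center/half-extent form."""
    c = 0.5 * (lo + hi)
    e = 0.5 * (hi - lo)
    c2 = R @ c + t
    e2 = np.abs(R) @ e
    return c2 - e2, c2 + e2


def query_pairs(treeA: AABBTree, treeB: AABBTree, R_AB: np.ndarray,
                t_AB: np.ndarray, inflate: float = 0.0) -> np.ndarray:
    """Dual-tree descent: candidate (triA, triB) pairs whose boxes overlap.

    Tree B's boxes are mapped into A's frame with the rigid transform
    ``x_A = R_AB x_B + t_AB`` (conservatively re-axis-aligned).  The descent
    is level-synchronous and vectorized over the active pair front.
    """
    # B boxes in A frame, in center/half-extent form (vectorized once).
    # The reconstruction c +- e rounds, so pad by a few ulp to keep exactly
    # touching boxes (the candidate set must be a superset).
    cB = 0.5 * (treeB.lower + treeB.upper) @ R_AB.T + t_AB
    fp_pad = 1e-12 * (1.0 + np.abs(cB).max())
    eB = 0.5 * (treeB.upper - treeB.lower) @ np.abs(R_AB).T + inflate + fp_pad

    ia = np.zeros(1, np.int64)
    ib = np.zeros(1, np.int64)
    out_a: List[np.ndarray] = []
    out_b: List[np.ndarray] = []
    while len(ia):
        blo = cB[ib] - eB[ib]
        bhi = cB[ib] + eB[ib]
        hit = np.all((treeA.upper[ia] >= blo) & (treeA.lower[ia] <= bhi), axis=1)
        ia, ib = ia[hit], ib[hit]
        if not len(ia):
            break
        leafA = treeA.left[ia] < 0
        leafB = treeB.left[ib] < 0
        done = leafA & leafB
        if np.any(done):
            out_a.append(treeA.tri[ia[done]])
            out_b.append(treeB.tri[ib[done]])
        rest = ~done
        ia, ib = ia[rest], ib[rest]
        if not len(ia):
            break
        # split A where A is internal and (B is a leaf or A's box is larger)
        szA = np.sum(treeA.upper[ia] - treeA.lower[ia], axis=1)
        szB = 2.0 * np.sum(eB[ib], axis=1)
        splitA = (treeA.left[ia] >= 0) & ((treeB.left[ib] < 0) | (szA >= szB))
        a1 = np.concatenate([treeA.left[ia[splitA]], treeA.right[ia[splitA]],
                             ia[~splitA], ia[~splitA]])
        b1 = np.concatenate([ib[splitA], ib[splitA],
                             treeB.left[ib[~splitA]], treeB.right[ib[~splitA]]])
        ia, ib = a1, b1
    if not out_a:
        return np.empty((0, 2), np.int64)
    return np.stack([np.concatenate(out_a), np.concatenate(out_b)], axis=1)
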