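"""Mesh-to-mesh contact backend.

Contacts between two posed triangle meshes (femoral surface vs patellar
button) are found by dual AABB-tree descent, triangle-pair intersection,
and chaining of the intersection segments into closed contact contours.
Per contour the backend reports the averaged contact point (length-weighted
contour centroid), the area-weighted mean normal of the intersected femur
faces, and the maximum indentation — the largest depth of a penetrated
patella vertex below the femur surface.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Tuple

import numpy as np

from ..geometry import TriMesh
from .aabb import AABBTree, build_aabb_tree, query_candidates
from .contact import ContactPatch, EpisodeTracker
from .tritri import point_triangle_closest, tri_tri_segments_batch

__all__ = ["MeshContactBackend", "mesh_contacts", "dump_contours_obj"]

Pose = Tuple[np.ndarray, np.ndarray]      # (R, r): x_world = R x_body + r


def _chain_contours(segments: List[Tuple[np.ndarray, np.ndarray]],
                    quantum: float = 1e-9):
    """Chain intersection segments into closed polylines.

    Endpoints are matched by quantizing coordinates to ``quantum``.
    Returns (closed contours, open chains); each contour/chain is a list of
    segment indices in traversal order.
    """
    ends = np.array([[p0, p1] for p0, p1 in segments])     # (n, 2, 3)
    qkeys = np.round(ends / quantum).astype(np.int64)
    keys = [[tuple(qkeys[i, 0]), tuple(qkeys[i, 1])] for i in range(len(segments))]
    adj = {}
    for i in range(len(segments)):
        adj.setdefault(keys[i][0], []).append((i, 0))
        adj.setdefault(keys[i][1], []).append((i, 1))

    visited = [False] * len(segments)
    closed, open_ = [], []
    for start in range(len(segments)):
        if visited[start]:
            continue
        chain = [start]
        visited[start] = True
        is_closed = False
        # walk forward from endpoint 1, then backward from endpoint 0
        for direction in (1, 0):
            cur, end = start, direction
            while True:
                k = keys[cur][end]
                nxt = [(i, e) for (i, e) in adj.get(k, []) if not visited[i]]
                if not nxt:
                    # closed if we returned to the free end of the start segment
                    back = [(i, e) for (i, e) in adj.get(k, []) if i == start]
                    if direction == 1 and any(e == 0 for (_, e) in back) and len(chain) > 1:
                        is_closed = True
                    break
                cur, came = nxt[0]
                visited[cur] = True
                if direction == 1:
                    chain.append(cur)
                else:
                    chain.insert(0, cur)
                end = 1 - came
            if is_closed:
                break
        (closed if is_closed else open_).append(chain)
    return closed, open_


class MeshContactBackend:
    """Stateful mesh-mesh contact detector for a femur/patella mesh pair.

    Trees are built once in each body frame; poses are applied per query.
    Episode bookkeeping (``delta_dot0`` latching) is internal — call
    :meth:`reset` between independent simulations.
    """

    #: integrator steps recommended for this backend (s)
    default_timestep = 1e-4
    reduced_timestep = 5e-5

    def __init__(self, femur_mesh: TriMesh, patella_mesh: TriMesh,
                 match_radius: float = 0.01, depth_margin: float = 0.005):
        self.femur = femur_mesh
        self.patella = patella_mesh
        self.tree_f: AABBTree = build_aabb_tree(femur_mesh)
        self.tree_p: AABBTree = build_aabb_tree(patella_mesh)
        self.episodes = EpisodeTracker(match_radius=match_radius)
        self.depth_margin = float(depth_margin)

    def reset(self) -> None:
        self.episodes.reset()

    def contacts(self, pose_femur: Pose, pose_patella: Pose,
                 vel_femur=None, vel_patella=None, t: float = 0.0,
                 track_episodes: bool = True) -> List[ContactPatch]:
        """Contact patches (world frame) between the posed meshes.

        ``vel_*`` are optional (linear velocity, angular velocity) world
        twists used for the normal approach rate.
        """
        Rf, rf = (np.asarray(a, float) for a in pose_femur)
        Rp, rp = (np.asarray(a, float) for a in pose_patella)
        R_fp = Rf.T @ Rp
        t_fp = Rf.T @ (rp - rf)

        # broad phase: femur triangles near the patella's AABB, then exact
        # per-pair box overlap (the button is small, so this beats a full
        # dual-tree descent from the roots at every query)
        verts_p = self.patella.vertices @ R_fp.T + t_fp
        lo_p_all = verts_p.min(axis=0)
        hi_p_all = verts_p.max(axis=0)
        f_ids = query_candidates(self.tree_f, lo_p_all, hi_p_all)
        patches: List[ContactPatch] = []
        if len(f_ids):
            tri_p = verts_p[self.patella.faces]
            lo_p = tri_p.min(axis=1)
            hi_p = tri_p.max(axis=1)
            # iteratively shrink both candidate sets to the mutual overlap
            # region before the O(N*M) pair test (the contact zone is a
            # small part of either surface)
            keep_p = np.arange(len(lo_p))
            for _ in range(3):
                if not (len(f_ids) and len(keep_p)):
                    break
                flo = self.tree_f.tri_lower[f_ids].min(axis=0)
                fhi = self.tree_f.tri_upper[f_ids].max(axis=0)
                sel = np.all((hi_p[keep_p] >= flo) & (lo_p[keep_p] <= fhi),
                             axis=1)
                if sel.all() and len(f_ids) < 1000:
                    break
                keep_p = keep_p[sel]
                if not len(keep_p):
                    break
                plo = lo_p[keep_p].min(axis=0)
                phi = hi_p[keep_p].max(axis=0)
                f_ids = query_candidates(self.tree_f, plo, phi)
            if len(f_ids) and len(keep_p):
                lo_f = self.tree_f.tri_lower[f_ids]
                hi_f = self.tree_f.tri_upper[f_ids]
                hit = np.all((hi_f[:, None] >= lo_p[keep_p][None]) &
                             (lo_f[:, None] <= hi_p[keep_p][None]), axis=2)
                ia, ib = np.nonzero(hit)
                pairs = np.stack([f_ids[ia], keep_p[ib]], axis=1)
                if len(pairs):
                    patches = self._patches_femur_frame(pairs, R_fp, t_fp,
                                                        verts_p=verts_p,
                                                        tri_p=tri_p)
            for p in patches:
                p.point = Rf @ p.point + rf
                p.normal = Rf @ p.normal
                if p.contour is not None:
                    p.contour = [c @ Rf.T + rf for c in p.contour]
                p.delta_dot = self._approach_rate(p, (Rf, rf), (Rp, rp),
                                                  vel_femur, vel_patella)
        if track_episodes:
            self.episodes.update(patches, t)
        return patches

    # ---- internals --------------------------------------------------------

    def _patches_femur_frame(self, pairs, R_fp, t_fp, verts_p=None,
                             tri_p=None) -> List[ContactPatch]:
        if verts_p is None:
            verts_p = self.patella.vertices @ R_fp.T + t_fp
        if tri_p is None:
            tri_p = verts_p[self.patella.faces]
        tri_f = self.femur.triangles

        p0, p1, which = tri_tri_segments_batch(tri_f[pairs[:, 0]],
                                               tri_p[pairs[:, 1]])
        if not len(which):
            return []
        keep = np.linalg.norm(p1 - p0, axis=1) > 1e-12
        segments = [(a, b) for a, b in zip(p0[keep], p1[keep])]
        seg_faces = [(int(ia), int(ib)) for ia, ib in pairs[which[keep]]]
        if not segments:
            return []

        closed, open_ = _chain_contours(segments)
        if open_ and not closed:
            warnings.warn("open contact contour; falling back to deepest-point "
                          "contact", RuntimeWarning, stacklevel=2)
            closed = [sorted({i for ch in open_ for i in ch})]
        elif open_:
            # stray open chains alongside closed contours: fold the longest
            closed = closed

        patches = []
        for chain in closed:
            patches.append(self._contour_patch(chain, segments, seg_faces,
                                               verts_p))
        return [p for p in patches if p is not None]

    def _contour_patch(self, chain, segments, seg_faces, verts_p
                       ) -> Optional[ContactPatch]:
        segs = [segments[i] for i in chain]
        mids = np.array([0.5 * (s[0] + s[1]) for s in segs])
        lens = np.array([np.linalg.norm(s[1] - s[0]) for s in segs])
        total = lens.sum()
        if total <= 0:
            return None
        centroid = (mids * lens[:, None]).sum(axis=0) / total

        f_faces = sorted({seg_faces[i][0] for i in chain})
        p_faces = sorted({seg_faces[i][1] for i in chain})
        areas = self.femur.face_areas[f_faces]
        normal = (self.femur.face_normals[f_faces] * areas[:, None]).sum(axis=0)
        nn = np.linalg.norm(normal)
        if nn == 0:
            return None
        normal = normal / nn

        delta = self._max_indentation(centroid, segs, p_faces, verts_p, normal)
        contour = [np.array([s[0] for s in segs] + [segs[-1][1]])]
        return ContactPatch(point=centroid, normal=normal, delta=max(delta, 0.0),
                            contour=contour)

    def _max_indentation(self, centroid, segs, p_faces, verts_p, normal):
        """Largest depth of a penetrated patella vertex below the femur
        surface (signed by the local femur face normal)."""
        pts = np.array([p for s in segs for p in s])
        # the penetrated cap extends ~ one contour extent along -normal;
        # laterally only a small guard band is needed
        extent = float(np.max(pts.max(0) - pts.min(0)))
        margin = 0.001 + (self.depth_margin + 0.6 * extent) * np.abs(normal)
        lo = pts.min(axis=0) - margin
        hi = pts.max(axis=0) + margin

        sel = np.all((verts_p >= lo) & (verts_p <= hi), axis=1)
        cand_v = verts_p[sel]
        if len(cand_v):
            # only vertices on the femur side of the contour plane can penetrate
            side = (cand_v - centroid) @ normal
            cand_v = cand_v[side < self.depth_margin]
        if not len(cand_v):
            return 0.0

        f_ids = query_candidates(self.tree_f, lo, hi)
        if not len(f_ids):
            return 0.0
        tri_f = self.femur.triangles[f_ids]
        dist, closest = point_triangle_closest(cand_v, tri_f)
        j = np.argmin(dist, axis=1)
        rows = np.arange(len(cand_v))
        cp = closest[rows, j]
        fn = self.femur.face_normals[f_ids][j]
        signed = np.sum((cand_v - cp) * fn, axis=1)
        depth = -signed
        return float(depth.max()) if np.any(depth > 0) else 0.0

    @staticmethod
    def _approach_rate(patch, pose_f, pose_p, vel_f, vel_p) -> float:
        if vel_f is None and vel_p is None:
            return 0.0
        pt = patch.point
        vf = np.zeros(3) if vel_f is None else (
            np.asarray(vel_f[0], float)
            + np.cross(np.asarray(vel_f[1], float), pt - pose_f[1]))
        vp = np.zeros(3) if vel_p is None else (
            np.asarray(vel_p[0], float)
            + np.cross(np.asarray(vel_p[1], float), pt - pose_p[1]))
        # delta grows when the patella moves against the outward femur normal
        return float(patch.normal @ (vf - vp))


def dump_contours_obj(patches, path) -> None:
    """Debug dump: contact contours as OBJ polylines."""
    with open(path, "w") as fh:
        base = 1
        for k, p in enumerate(patches):
            for contour in (p.contour or []):
                fh.write(f"o contour_{k}\n")
                for v in contour:
                    fh.write(f"v {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
                idx = " ".join(str(base + i) for i in range(len(contour)))
                fh.write(f"l {idx}\n")
                base += len(contour)


def mesh_contacts(femur_mesh: TriMesh, patella_mesh: TriMesh,
                  pose_femur: Pose, pose_patella: Pose,
                  vel_femur=None, vel_patella=None,
                  backend: Optional[MeshContactBackend] = None,
                  t: float = 0.0) -> List[ContactPatch]:
    """One-shot functional wrapper over :class:`MeshContactBackend`."""
    if backend is None:
        backend = MeshContactBackend(femur_mesh, patella_mesh)
    return backend.contacts(pose_femur, pose_patella, vel_femur, vel_patella, t=t)
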