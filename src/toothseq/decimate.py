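"""Fixed-budget mesh simplification by quadric-error-metric edge collapse.

The encoder consumes a fixed number of triangles per tooth (900 by default),
so the simplifier must land on the budget *exactly*, not approximately.
Strategy:

1. Greedy QEM edge collapse (Garland–Heckbert plane quadrics) until the face
   count first reaches ``target_faces`` or would undershoot it. Collapse
   placement picks the cheapest of the candidate set {v_i, v_j, midpoint}
   under the summed quadric, which keeps cost evaluation fully vectorized and
   deterministic.
2. If skips (link-condition / flip rejections) leave the count below target,
   longest-edge splits add faces back (+2 per interior edge, +1 per boundary
   edge) until the count is exact.

Collapses that would change topology (link condition) or flip a face normal
are rejected. Everything is deterministic: ties in the priority queue break
on (cost, vertex indices).

A closed manifold mesh always has an even face count and collapses/splits
preserve that parity, so an *odd* target on a closed mesh is unreachable and
raises.
"""

from __future__ import annotations

import heapq
from collections import defaultdict
from typing import Dict, List, Set, Tuple

import numpy as np

from .mesh import MeshValidationError, TriMesh

__all__ = ["decimate_mesh"]


def _face_quadrics(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Fundamental error quadric K_p = p p^T of each face's plane."""
    a, b, c = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    n = np.cross(b - a, c - a)
    area2 = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.where(area2 > 1e-300, area2, 1.0)
    d = -np.einsum("ij,ij->i", n, a)
    p = np.hstack([n, d[:, None]])  # (m, 4) plane coefficients
    return np.einsum("mi,mj->mij", p, p)


def _edge_costs(
    Q: np.ndarray, V: np.ndarray, I: np.ndarray, J: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Cost and placement for each candidate edge (vectorized).

    Placement is the cheapest of {V[i], V[j], midpoint} under Q_i + Q_j; on
    ties the earlier candidate wins (deterministic).
    """
    Qe = Q[I] + Q[J]
    vi, vj = V[I], V[J]
    cand = np.stack([vi, vj, 0.5 * (vi + vj)], axis=1)  # (k, 3, 3)
    hom = np.concatenate([cand, np.ones(cand.shape[:2] + (1,))], axis=2)
    cost = np.einsum("kca,kab,kcb->kc", hom, Qe, hom)
    pick = np.argmin(cost, axis=1)
    k = np.arange(len(I))
    return cost[k, pick], cand[k, pick]


def _unique_edges(F: np.ndarray) -> np.ndarray:
    e = np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


class _Decimator:
    def __init__(self, mesh: TriMesh):
        self.V = mesh.vertices.copy()
        self.Q = np.zeros((len(self.V), 4, 4))
        fq = _face_quadrics(self.V, mesh.faces)
        for col in range(3):
            np.add.at(self.Q, mesh.faces[:, col], fq)
        # faces keyed by original index; dict order == face order
        self.faces: Dict[int, Tuple[int, int, int]] = {
            i: tuple(f) for i, f in enumerate(mesh.faces.tolist())
        }
        self.vfaces: Dict[int, Set[int]] = defaultdict(set)
        for fid, (a, b, c) in self.faces.items():
            self.vfaces[a].add(fid)
            self.vfaces[b].add(fid)
            self.vfaces[c].add(fid)
        self.version = np.zeros(len(self.V), dtype=np.int64)
        self.heap: List[tuple] = []

    # -- queue maintenance --------------------------------------------------

    def _push_edges(self, I: np.ndarray, J: np.ndarray) -> None:
        if len(I) == 0:
            return
        lo, hi = np.minimum(I, J), np.maximum(I, J)
        cost, place = _edge_costs(self.Q, self.V, lo, hi)
        for k in range(len(lo)):
            i, j = int(lo[k]), int(hi[k])
            heapq.heappush(
                self.heap,
                (
                    float(cost[k]),
                    i,
                    j,
                    int(self.version[i]),
                    int(self.version[j]),
                    place[k, 0],
                    place[k, 1],
                    place[k, 2],
                ),
            )

    def _seed_queue(self) -> None:
        F = np.array(list(self.faces.values()), dtype=np.int64)
        e = _unique_edges(F)
        self.heap = []
        self._push_edges(e[:, 0], e[:, 1])

    def _neighbors(self, v: int) -> Set[int]:
        out: Set[int] = set()
        for fid in self.vfaces[v]:
            out.update(self.faces[fid])
        out.discard(v)
        return out

    # -- collapse -----------------------------------------------------------

    def _try_collapse(self, i: int, j: int, p: np.ndarray) -> bool:
        fi, fj = self.vfaces[i], self.vfaces[j]
        shared = fi & fj
        if not shared:
            return False  # stale: no longer an edge
        # link condition: common neighbors must be exactly the vertices
        # opposite the shared faces, otherwise the collapse pinches the mesh
        opp = set()
        for fid in shared:
            opp.update(self.faces[fid])
        opp -= {i, j}
        if (self._neighbors(i) & self._neighbors(j)) - opp:
            return False
        # normal-flip check over surviving incident faces
        affected = [fid for fid in (fi | fj) - shared]
        if affected:
            tris = np.array([self.faces[fid] for fid in affected])
            old = self.V[tris]
            new = old.copy()
            for col in range(3):
                mask = (tris[:, col] == i) | (tris[:, col] == j)
                new[mask, col] = p
            n_old = np.cross(old[:, 1] - old[:, 0], old[:, 2] - old[:, 0])
            n_new = np.cross(new[:, 1] - new[:, 0], new[:, 2] - new[:, 0])
            if (np.einsum("ij,ij->i", n_old, n_new) <= 0).any():
                return False
        # apply
        for fid in list(shared):
            for v in self.faces[fid]:
                self.vfaces[v].discard(fid)
            del self.faces[fid]
        for fid in list(fj):
            a, b, c = self.faces[fid]
            self.faces[fid] = tuple(i if v == j else v for v in (a, b, c))
            self.vfaces[i].add(fid)
        self.vfaces[j] = set()
        self.V[i] = p
        self.Q[i] = self.Q[i] + self.Q[j]
        self.version[i] += 1
        self.version[j] += 1
        nbrs = np.array(sorted(self._neighbors(i)), dtype=np.int64)
        self._push_edges(np.full(len(nbrs), i, dtype=np.int64), nbrs)
        return True

    def collapse_to(self, target: int) -> None:
        self._seed_queue()
        stale_rebuild = False
        while len(self.faces) > target:
            if not self.heap:
                if stale_rebuild:
                    raise RuntimeError(
                        "decimation stalled: no collapsible edge remains "
                        f"above the target ({len(self.faces)} > {target})"
                    )
                self._seed_queue()
                stale_rebuild = True
                continue
            cost, i, j, vi, vj, px, py, pz = heapq.heappop(self.heap)
            if self.version[i] != vi or self.version[j] != vj:
                continue
            if self._try_collapse(i, j, np.array([px, py, pz])):
                stale_rebuild = False

    # -- refinement back up to the exact budget -----------------------------

    def split_to(self, target: int) -> None:
        next_fid = max(self.faces) + 1 if self.faces else 0
        while len(self.faces) < target:
            deficit = target - len(self.faces)
            F = np.array(list(self.faces.values()), dtype=np.int64)
            fids = np.array(list(self.faces.keys()), dtype=np.int64)
            e = np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
            e.sort(axis=1)
            uniq, counts = np.unique(e, axis=0, return_counts=True)
            lengths = np.linalg.norm(self.V[uniq[:, 0]] - self.V[uniq[:, 1]], axis=1)
            # an interior edge split adds 2 faces, a boundary split adds 1
            if deficit == 1:
                sel = counts == 1
                if not sel.any():
                    raise MeshValidationError(
                        "cannot reach an odd face target on a closed mesh "
                        "(face parity is even)"
                    )
                cand_idx = np.where(sel)[0]
            else:
                cand_idx = np.arange(len(uniq))
            pick = cand_idx[np.argmax(lengths[cand_idx])]
            a, b = int(uniq[pick, 0]), int(uniq[pick, 1])
            mid = 0.5 * (self.V[a] + self.V[b])
            m = len(self.V)
            self.V = np.vstack([self.V, mid])
            self.Q = np.concatenate([self.Q, np.zeros((1, 4, 4))])
            self.version = np.append(self.version, 0)
            incident = [
                int(fids[k])
                for k in np.where(
                    ((F == a).any(axis=1)) & ((F == b).any(axis=1))
                )[0]
            ]
            for fid in incident:
                tri = self.faces[fid]
                # replace (…a…b…) face with two children sharing the midpoint
                t1 = tuple(m if v == b else v for v in tri)
                t2 = tuple(m if v == a else v for v in tri)
                for v in tri:
                    self.vfaces[v].discard(fid)
                del self.faces[fid]
                for t in (t1, t2):
                    self.faces[next_fid] = t
                    for v in t:
                        self.vfaces[v].add(next_fid)
                    next_fid += 1

    def result(self, label, source_id) -> TriMesh:
        fids = sorted(self.faces)
        F = np.array([self.faces[f] for f in fids], dtype=np.int64)
        used = np.unique(F)
        remap = np.full(len(self.V), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriMesh(self.V[used], remap[F], label=label, source_id=source_id)


def decimate_mesh(
    mesh: TriMesh, target_faces: int, on_deficit: str = "error"
) -> TriMesh:
    """Simplify ``mesh`` to exactly ``target_faces`` triangles.

    Parameters
    ----------
    mesh : TriMesh
        Input surface; must satisfy the mesh invariants.
    target_faces : int
        The triangle budget. The result has exactly this many faces.
    on_deficit : {"error", "pass", "split"}
        What to do when the input already has *fewer* faces than the budget:
        raise (default), return the mesh unchanged, or upsample by
        longest-edge splitting until the budget is met.

    Notes
    -----
    Deterministic: identical input yields an identical output mesh. Label and
    source_id are carried through.
    """
    mesh.validate()
    if target_faces < 1:
        raise ValueError("target_faces must be >= 1")
    if mesh.n_faces == target_faces:
        return mesh.copy()
    if mesh.n_faces < target_faces:
        if on_deficit == "pass":
            return mesh.copy()
        if on_deficit == "split":
            d = _Decimator(mesh)
            d.split_to(target_faces)
            return d.result(mesh.label, mesh.source_id).validate()
        raise ValueError(
            f"mesh has {mesh.n_faces} faces, fewer than the target "
            f"{target_faces}; subdivide first or pass on_deficit='pass'/'split'"
        )
    d = _Decimator(mesh)
    d.collapse_to(target_faces)
    if len(d.faces) < target_faces:
        d.split_to(target_faces)
    out = d.result(mesh.label, mesh.source_id).validate()
    assert out.n_faces == target_faces
    return out
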