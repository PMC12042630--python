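"""Triangular surface mesh container.

A mesh is the pair M = (V, F): vertices V as points in R^3 (scanner length
units, typically mm) and faces F as triples of 0-based vertex indices. This is
the common currency of every stage in the package: generation, decimation,
rigid-motion augmentation and feature encoding all consume and produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["TriMesh", "MeshValidationError"]


class MeshValidationError(ValueError):
    """Raised when vertex/face arrays violate the mesh invariants."""


@dataclass
class TriMesh:
    """An isolated tooth surface (or any triangular mesh).

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates. Order is meaningful and preserved by I/O.
    faces : (m, 3) int array
        Vertex-index triples, 0-based internally (converted at format
        boundaries). Order is meaningful: the encoder emits one image row per
        face in stored order.
    label : str, optional
        Tooth-type identifier (one of the 16 canonical names, or a collapsed
        category).
    source_id : str, optional
        Provenance string, e.g. ``"s03_1st Molar (L)#v2"`` for subject 3's
        left first molar, augmentation variant 2.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: Optional[str] = None
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)

    # -- invariants ---------------------------------------------------------

    def validate(self) -> "TriMesh":
        """Check all invariants; return self or raise MeshValidationError."""
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshValidationError(f"faces must be (m, 3), got {f.shape}")
        if len(v) < 3:
            raise MeshValidationError(f"need at least 3 vertices, got {len(v)}")
        if len(f) < 1:
            raise MeshValidationError("need at least 1 face")
        if not np.isfinite(v).all():
            raise MeshValidationError("vertex coordinates contain NaN or inf")
        if f.min(initial=0) < 0 or f.max(initial=-1) >= len(v):
            bad = int(np.where((f < 0) | (f >= len(v)))[0][0])
            raise MeshValidationError(
                f"face {bad} has a vertex index outside [0, {len(v)})"
            )
        degenerate = (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        )
        if degenerate.any():
            bad = int(np.where(degenerate)[0][0])
            raise MeshValidationError(f"face {bad} repeats a vertex index")
        return self

    # -- conveniences -------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(), self.faces.copy(), self.label, self.source_id
        )

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        """New mesh with replaced coordinates, same connectivity and metadata."""
        return TriMesh(np.asarray(vertices), self.faces.copy(), self.label, self.source_id)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of per-axis min / max."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def bbox_diagonal(self) -> float:
        lo, hi = self.bounds()
        return float(np.linalg.norm(hi - lo))

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)
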