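"""Rigid-motion data augmentation: rotation and translation of tooth meshes.

The rotation operator is the study's printed one-angle matrix R(a), whose
nine trigonometric entries are reproduced verbatim here; algebraically it is
the extrinsic equal-angle Euler composition R_z(a)·R_y(a)·R_x(a) (a property
the test suite verifies numerically). A "triple" mode with three independent
Euler angles is exposed for the alternative reading of the operator.
Translations add a per-axis offset drawn from [0, 90] (scanner units).

Angles are degrees throughout; conversion to radians happens only inside the
trigonometric evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .mesh import TriMesh

__all__ = [
    "RotationSpec",
    "TranslationSpec",
    "AugmentationPolicy",
    "rotation_matrix",
    "apply_rotation",
    "apply_translation",
    "augment_dataset",
]


def _wrap(angle: float) -> float:
    return float(np.mod(angle, 360.0))


@dataclass
class RotationSpec:
    """A rotation by Euler angles in degrees.

    mode="single": the printed one-angle matrix, all three Euler angles equal
    to ``alpha``. mode="triple": independent angles composed extrinsically as
    R_z(az)·R_y(ay)·R_x(ax).
    """

    alpha: float = 0.0
    mode: str = "single"
    angles_xyz: Tuple[float, float, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mode not in ("single", "triple"):
            raise ValueError(f"unknown rotation mode {self.mode!r}")
        self.alpha = _wrap(self.alpha)
        if self.mode == "single":
            self.angles_xyz = (self.alpha, self.alpha, self.alpha)
        else:
            if self.angles_xyz is None:
                raise ValueError("triple mode requires angles_xyz")
            self.angles_xyz = tuple(_wrap(a) for a in self.angles_xyz)


@dataclass
class TranslationSpec:
    """A per-axis offset (t_x, t_y, t_z) in scanner units."""

    t: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.t = tuple(float(x) for x in self.t)
        if len(self.t) != 3:
            raise ValueError("translation must have exactly 3 components")


@dataclass
class AugmentationPolicy:
    """Dataset-expansion policy.

    ``variants_per_original`` counts every object emitted per input,
    *including* the untransformed identity copy (variant 0); the default 6
    expands 448 originals to 2688 objects. Random draws come from a seeded
    generator with a fixed stream order: per mesh, per variant, rotation
    angle(s) first, then the three translation components.
    """

    variants_per_original: int = 6
    angle_range: Tuple[float, float] = (0.0, 360.0)
    translation_range: Tuple[float, float] = (0.0, 90.0)
    seed: int = 0
    rotation_mode: str = "single"

    def __post_init__(self) -> None:
        if self.variants_per_original < 1:
            raise ValueError("variants_per_original must be >= 1")
        if self.rotation_mode not in ("single", "triple"):
            raise ValueError(f"unknown rotation mode {self.rotation_mode!r}")


def rotation_matrix(spec: RotationSpec) -> np.ndarray:
    """The 3x3 rotation matrix of a spec.

    Single mode evaluates the printed entry formulas exactly; triple mode
    composes the elementary rotations R_z·R_y·R_x.
    """
    if spec.mode == "single":
        a = np.deg2rad(spec.alpha)
        c, s = np.cos(a), np.sin(a)
        return np.array(
            [
                [c * c, c * (s * s - s), c * c * s + s * s],
                [c * s, s**3 + c * c, c * (s * s - s)],
                [-s, s * c, c * c],
            ]
        )
    ax, ay, az = np.deg2rad(spec.angles_xyz)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def apply_rotation(mesh: TriMesh, spec: RotationSpec) -> TriMesh:
    """Rotate vertices: V' = (R · V^T)^T. Connectivity and metadata unchanged."""
    R = rotation_matrix(spec)
    return mesh.with_vertices((R @ mesh.vertices.T).T)


def apply_translation(mesh: TriMesh, spec: TranslationSpec) -> TriMesh:
    """Translate every vertex by t (the homogeneous-matrix shift)."""
    return mesh.with_vertices(mesh.vertices + np.asarray(spec.t))


def _draw_rotation(rng: np.random.Generator, policy: AugmentationPolicy) -> RotationSpec:
    lo, hi = policy.angle_range
    if policy.rotation_mode == "single":
        return RotationSpec(alpha=float(rng.uniform(lo, hi)), mode="single")
    return RotationSpec(mode="triple", angles_xyz=tuple(rng.uniform(lo, hi, 3)))


def augment_dataset(
    meshes: Sequence[TriMesh], policy: AugmentationPolicy
) -> List[TriMesh]:
    """Expand each mesh into ``variants_per_original`` objects.

    Variant 0 is the untransformed original; every later variant applies one
    random rotation followed by one random translation. Labels are inherited;
    source_id gains a ``#v<k>`` suffix. Fully reproducible given the seed.
    """
    rng = np.random.default_rng(policy.seed)
    lo_t, hi_t = policy.translation_range
    out: List[TriMesh] = []
    for mesh in meshes:
        base = mesh.source_id or ""
        for k in range(policy.variants_per_original):
            if k == 0:
                variant = mesh.copy()
            else:
                rot = _draw_rotation(rng, policy)
                shift = TranslationSpec(tuple(rng.uniform(lo_t, hi_t, 3)))
                variant = apply_translation(apply_rotation(mesh, rot), shift)
            variant.source_id = f"{base}#v{k}"
            out.append(variant)
    return out
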