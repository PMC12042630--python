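"""Synthetic tooth-crown generator: a testable stand-in for scan data.

Real intraoral-scan tooth meshes are not redistributable, so this module
fabricates labeled, class-separable, tooth-*like* crowns that exercise every
pipeline stage at realistic mesh densities. Each of the 8 maxillary
anatomical types is a superellipsoid crown (class-specific width/depth/height
aspect and squareness) carrying a class-specific number of Gaussian cusp
bumps on its occlusal (top) face; right-side teeth are the mirror image of
left-side ones. Per-subject variation multiplies every shape parameter by
(1 + N(0, jitter)).

The geometry is deliberately parametric, not anatomical: it optimizes for a
class-separable signal, controllable face counts and bitwise determinism,
which is what the pipeline's tests need. Linear units are millimetres
(crowns span roughly 6–11 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .labels import CANONICAL_16
from .mesh import TriMesh

__all__ = [
    "ToothClassSpec",
    "SyntheticDatasetConfig",
    "generate_tooth",
    "generate_dataset",
    "class_specs_16",
    "write_dataset",
]


@dataclass(frozen=True)
class ToothClassSpec:
    """Geometry recipe for one of the 16 sided tooth classes.

    cusp_count: bumps on the occlusal face (incisors 0–1, canine 1,
    premolars 2, molars 3–4). crown_aspect: (width, depth, height) half-extent
    ratios. squareness: superellipsoid exponent (<1 is boxier). cusp_amp:
    bump height in mm. mirror: right-side teeth, reflected across x.
    """

    class_name: str
    cusp_count: int
    crown_aspect: Tuple[float, float, float]
    squareness: float = 0.85
    cusp_amp: float = 1.1
    cusp_sigma: float = 0.18
    mirror: bool = False

    def __post_init__(self) -> None:
        if self.cusp_count < 0:
            raise ValueError("cusp_count must be >= 0")


# (cusp_count, aspect (w, d, h), squareness, cusp_amp) per anatomical type.
# Signatures are pairwise distinct so that even the 16-way task is winnable.
_ANATOMY = {
    "Central Incisor": (0, (1.00, 0.45, 1.35), 0.70, 0.0),
    "Lateral Incisor": (1, (0.82, 0.42, 1.18), 0.75, 0.55),
    "Canine": (1, (0.92, 0.62, 1.50), 0.90, 2.0),
    "1st Premolar": (2, (1.00, 0.88, 1.00), 0.85, 1.25),
    "2nd Premolar": (2, (1.06, 0.96, 0.90), 0.80, 1.15),
    "1st Molar": (4, (1.34, 1.16, 0.78), 0.80, 1.10),
    "2nd Molar": (4, (1.20, 1.08, 0.72), 0.85, 1.00),
    "3rd Molar": (3, (1.08, 1.02, 0.66), 0.90, 0.95),
}


def class_specs_16() -> List[ToothClassSpec]:
    """The 16 canonical class specs, in canonical label order (L then R)."""
    specs = []
    for name in CANONICAL_16:
        anat, side = name[:-4], name[-2]
        cusps, aspect, sq, amp = _ANATOMY[anat]
        specs.append(
            ToothClassSpec(
                class_name=name,
                cusp_count=cusps,
                crown_aspect=aspect,
                squareness=sq,
                cusp_amp=amp,
                mirror=(side == "R"),
            )
        )
    return specs


@dataclass
class SyntheticDatasetConfig:
    """28 subjects × 16 tooth types by default → 448 meshes."""

    n_subjects: int = 28
    subject_jitter: float = 0.05
    dense_faces: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")


def _sphere_mesh(min_faces: int) -> _trimesh.Trimesh:
    """A sphere triangulation with at least ``min_faces`` faces.

    Icospheres give the most uniform triangles; their counts are 20·4^s, so a
    UV sphere fills the gaps when an exact-ish larger count is requested.
    """
    for s in range(8):
        if 20 * 4**s >= min_faces:
            if s <= 6:
                return _trimesh.creation.icosphere(subdivisions=s)
            break
    n = max(4, int(np.ceil(np.sqrt(min_faces / 4.0))))
    while True:
        m = _trimesh.creation.uv_sphere(count=(n, n))
        if len(m.faces) >= min_faces:
            return m
        n += 2


def _cusp_anchors(k: int, phase: float) -> np.ndarray:
    """Unit-square anchor positions of k cusps on the occlusal face."""
    if k == 0:
        return np.empty((0, 2))
    if k == 1:
        return np.zeros((1, 2))
    ang = 2.0 * np.pi * np.arange(k) / k + phase
    return 0.45 * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def generate_tooth(
    spec: ToothClassSpec,
    subject_jitter: float = 0.05,
    seed: int = 0,
    dense_faces: int = 20000,
) -> TriMesh:
    """Generate one tooth crown mesh. Deterministic given (spec, seed).

    The random draws (one per shape parameter, in a fixed order) happen
    before mirroring, so the right-side mesh of a spec is exactly the
    x-negation of its left-side counterpart at the same seed.
    """
    rng = np.random.default_rng(seed)
    base = _sphere_mesh(dense_faces)
    p = np.asarray(base.vertices, dtype=np.float64)

    aspect = np.asarray(spec.crown_aspect) * (
        1.0 + rng.normal(0.0, subject_jitter, 3)
    )
    squareness = spec.squareness * (1.0 + rng.normal(0.0, subject_jitter))
    amp = spec.cusp_amp * (1.0 + rng.normal(0.0, subject_jitter))
    sigma = spec.cusp_sigma * (1.0 + rng.normal(0.0, subject_jitter))
    phase = rng.uniform(0.0, 2.0 * np.pi)

    # superellipsoid morph of the unit sphere, then scale to mm half-extents
    q = np.sign(p) * np.abs(p) ** squareness
    half = 4.0 * aspect  # mm
    v = q * half

    anchors = _cusp_anchors(spec.cusp_count, phase) * half[:2]
    if len(anchors):
        w = np.clip(v[:, 2] / half[2], 0.0, 1.0) ** 2  # occlusal-side weight
        sig_mm = sigma * float(np.mean(half[:2]))
        d2 = ((v[:, None, :2] - anchors[None]) ** 2).sum(axis=2)
        bumps = np.exp(-d2 / (2.0 * sig_mm**2)).sum(axis=1)
        v = v.copy()
        v[:, 2] += amp * w * bumps

    if spec.mirror:
        v = v.copy()
        v[:, 0] = -v[:, 0]

    return TriMesh(
        v, np.asarray(base.faces, dtype=np.int64), label=spec.class_name
    ).validate()


def generate_dataset(cfg: SyntheticDatasetConfig):
    """Generate n_subjects × 16 labeled meshes and the matching label table.

    Left/right pairs of a subject share one random stream, so they are exact
    mirror images — like the two sides of a real dentition. Returns
    (meshes, labels DataFrame with columns file, label16, subject_id).
    """
    specs = class_specs_16()
    meshes: List[TriMesh] = []
    records = []
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects * 8)
    for s in range(cfg.n_subjects):
        for a, anat in enumerate(_ANATOMY):
            child_seed = streams[s * 8 + a]
            for spec in specs:
                if spec.class_name[:-4] != anat:
                    continue
                tooth_seed = int(child_seed.generate_state(1)[0] % (2**31))
                m = generate_tooth(
                    spec,
                    subject_jitter=cfg.subject_jitter,
                    seed=tooth_seed,
                    dense_faces=cfg.dense_faces,
                )
                m.source_id = f"s{s:02d}_{spec.class_name}"
                meshes.append(m)
                records.append(
                    {
                        "file": f"{m.source_id}.obj".replace(" ", "_"),
                        "label16": spec.class_name,
                        "subject_id": f"s{s:02d}",
                    }
                )
    return meshes, pd.DataFrame(records, columns=["file", "label16", "subject_id"])


def write_dataset(meshes: List[TriMesh], labels: pd.DataFrame, directory) -> None:
    """Write meshes as OBJ plus labels.csv (the CLI's output layout)."""
    from .io import save_mesh, write_labels

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for mesh, fname in zip(meshes, labels["file"]):
        save_mesh(mesh, directory / fname)
    write_labels(labels, directory / "labels.csv")
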