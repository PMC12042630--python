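"""Mesh-to-image encoding: one grayscale row per triangle.

Every triangle of a fixed-budget mesh contributes one row of a 2D feature
matrix: its three vertex coordinate triples (9 values) and its centroid
(3 values), in the column order

    v1x v1y v1z  v2x v2y v2z  v3x v3y v3z  cx cy cz

The matrix is min–max scaled *jointly* (one intensity scale over all entries,
as befits a single-channel grayscale image) to [0, 1]; the scaling bounds are
kept so the transform is invertible. Feature subsets — vertices only (9
columns) or centroids only (3 columns) — support the feature-ablation
experiments. Row order is the mesh's stored face order, which is therefore
part of the data contract; an optional canonical sort by centroid is
available for order-sensitivity experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, PngImagePlugin

from .mesh import TriMesh

__all__ = [
    "FeatureMatrix",
    "FeatureImage",
    "extract_features",
    "to_feature_image",
    "write_image",
    "read_image",
]

log = logging.getLogger(__name__)

SUBSETS = {"both": 12, "vertices": 9, "centers": 3}


@dataclass
class FeatureMatrix:
    """T×k matrix of raw per-triangle features (k = 12, 9 or 3)."""

    values: np.ndarray
    subset: str = "both"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}")


@dataclass
class FeatureImage:
    """A min–max normalized grayscale image of a feature matrix.

    float mode: pixels in [0, 1]; quantized mode: integers in [0, 255].
    ``norm_lo``/``norm_hi`` are the scaling bounds, kept for invertibility.
    """

    pixels: np.ndarray
    norm_lo: float
    norm_hi: float
    quantized: bool = False

    @property
    def shape(self):
        return self.pixels.shape

    def invert(self) -> np.ndarray:
        """Reconstruct the raw feature matrix (float mode: within 1e-9)."""
        scale = self.norm_hi - self.norm_lo
        p = self.pixels / 255.0 if self.quantized else self.pixels
        return p * scale + self.norm_lo


def extract_features(
    mesh: TriMesh,
    subset: str = "both",
    expected_faces: Optional[int] = None,
    strict: bool = True,
    canonical_order: bool = False,
) -> FeatureMatrix:
    """Build the per-triangle feature matrix of a mesh.

    Row i comes from face i in stored order (or centroid-sorted order when
    ``canonical_order``); vertex triples keep the face's stored index order.
    With ``expected_faces`` set, strict mode raises on a count mismatch while
    lenient mode zero-pads / truncates to the expected count.
    """
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {list(SUBSETS)}")
    mesh.validate()
    faces = mesh.faces
    if canonical_order:
        cen = mesh.vertices[faces].mean(axis=1)
        order = np.lexsort((cen[:, 0], cen[:, 1], cen[:, 2]))
        faces = faces[order]
    tri = mesh.vertices[faces]  # (T, 3, 3)
    verts = tri.reshape(len(faces), 9)
    centers = tri.mean(axis=1)
    if subset == "both":
        values = np.hstack([verts, centers])
    elif subset == "vertices":
        values = verts
    else:
        values = centers
    if expected_faces is not None and len(values) != expected_faces:
        if strict:
            raise ValueError(
                f"mesh has {len(values)} faces but the encoder expects "
                f"{expected_faces}"
            )
        log.warning(
            "face count %d != expected %d; %s",
            len(values),
            expected_faces,
            "truncating" if len(values) > expected_faces else "zero-padding",
        )
        if len(values) > expected_faces:
            values = values[:expected_faces]
        else:
            pad = np.zeros((expected_faces - len(values), values.shape[1]))
            values = np.vstack([values, pad])
    return FeatureMatrix(values, subset=subset)


def to_feature_image(fm: FeatureMatrix, quantize_8bit: bool = False) -> FeatureImage:
    """Joint min–max scale a feature matrix to grayscale.

    A constant matrix (degenerate range) maps to the all-zero image. The
    quantized mode rounds to nearest integer in [0, 255].
    """
    v = fm.values
    if not np.isfinite(v).all():
        raise ValueError("feature matrix contains NaN or inf")
    lo, hi = float(v.min()), float(v.max())
    if hi > lo:
        pixels = (v - lo) / (hi - lo)
    else:
        pixels = np.zeros_like(v)
    if quantize_8bit:
        pixels = np.rint(pixels * 255.0).astype(np.uint8)
    return FeatureImage(pixels, norm_lo=lo, norm_hi=hi, quantized=quantize_8bit)


def write_image(img: FeatureImage, path) -> None:
    """Serialize a feature image.

    Quantized images go to single-channel 8-bit grayscale PNG (with the
    scaling bounds in text chunks); float images go to an .npz array
    container, losslessly.
    """
    path = Path(path)
    if img.quantized:
        meta = PngImagePlugin.PngInfo()
        meta.add_text("norm_lo", repr(img.norm_lo))
        meta.add_text("norm_hi", repr(img.norm_hi))
        Image.fromarray(img.pixels.astype(np.uint8), mode="L").save(
            path, format="PNG", pnginfo=meta
        )
    else:
        np.savez(path, pixels=img.pixels, norm=np.array([img.norm_lo, img.norm_hi]))


def read_image(path) -> FeatureImage:
    """Read back a feature image written by :func:`write_image`."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".png":
            with Image.open(path) as im:
                pixels = np.asarray(im, dtype=np.uint8)
                lo = float(im.text.get("norm_lo", 0.0))
                hi = float(im.text.get("norm_hi", 1.0))
            return FeatureImage(pixels, norm_lo=lo, norm_hi=hi, quantized=True)
        with np.load(path) as data:
            lo, hi = data["norm"]
            return FeatureImage(
                data["pixels"], norm_lo=float(lo), norm_hi=float(hi), quantized=False
            )
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not read feature image {path}: {exc}") from exc
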