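"""Mesh and label-table I/O for OBJ, STL and PLY.

Format parsing and serialization are delegated to ``trimesh``; this module
adds the package's contracts on top: order preservation (``process=False``),
validation against the TriMesh invariants, an exact-coordinate weld for STL's
per-facet duplicated vertices, and the label CSV (columns
``file,label16,subject_id``).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .mesh import MeshValidationError, TriMesh

__all__ = ["load_mesh", "save_mesh", "read_labels", "write_labels", "FORMATS"]

FORMATS = ("obj", "stl", "ply")

PathLike = Union[str, os.PathLike]


def _format_from_path(path: PathLike, fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower().lstrip(".")
    else:
        fmt = Path(path).suffix.lower().lstrip(".")
    if fmt not in FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {FORMATS}")
    return fmt


def _weld_exact(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices with bit-identical coordinates, keeping first-seen order.

    STL stores three independent vertices per facet; an exact weld (tolerance
    zero) reconstructs shared topology reproducibly.
    """
    _, first_idx, inverse = np.unique(
        vertices, axis=0, return_index=True, return_inverse=True
    )
    # np.unique sorts; remap so surviving vertices keep file order
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    welded = vertices[np.sort(first_idx)]
    return welded, rank[inverse][faces]


def load_mesh(path: PathLike, format: Optional[str] = None) -> TriMesh:
    """Read a triangular mesh from OBJ, STL or PLY.

    The file's vertex and face order is preserved (no merging, sorting or
    repair); quadrilateral faces are triangulated by the reader. STL input is
    additionally welded at exact coordinate equality so that repeated facet
    corners become shared vertices.
    """
    fmt = _format_from_path(path, format)
    if not Path(path).is_file():
        raise IOError(f"mesh file not found: {path}")
    try:
        raw = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except MeshValidationError:
        raise
    except IndexError as exc:
        # the reader itself trips on a face referencing a missing vertex
        raise MeshValidationError(
            f"{path}: face vertex index out of range ({exc})"
        ) from exc
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise IOError(f"could not parse {path} as {fmt.upper()}: {exc}") from exc
    vertices = np.asarray(raw.vertices, dtype=np.float64)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if fmt == "stl":
        vertices, faces = _weld_exact(vertices, faces)
    return TriMesh(vertices, faces, source_id=Path(path).stem).validate()


def save_mesh(mesh: TriMesh, path: PathLike, format: Optional[str] = None) -> None:
    """Write a mesh to OBJ, ASCII/binary STL, or PLY.

    The mesh is validated before anything touches the disk; a reload through
    :func:`load_mesh` reproduces coordinates within 1e-6 and the identical
    face list.
    """
    fmt = _format_from_path(path, format)
    mesh.validate()
    out = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    try:
        out.export(str(path), file_type=fmt)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not write {path}: {exc}") from exc


def read_labels(path: PathLike) -> pd.DataFrame:
    """Read a label table CSV with columns ``file, label16, subject_id``."""
    df = pd.read_csv(path, dtype={"file": str, "label16": str, "subject_id": str})
    missing = {"file", "label16", "subject_id"} - set(df.columns)
    if missing:
        raise ValueError(f"label file {path} is missing columns {sorted(missing)}")
    return df


def write_labels(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False, columns=["file", "label16", "subject_id"])


def load_dataset(directory: PathLike, labels_csv: Optional[PathLike] = None):
    """Load every mesh referenced by a label CSV (default ``labels.csv``).

    Returns (meshes, labels DataFrame); each mesh gets its ``label16`` and a
    source_id of the file stem.
    """
    directory = Path(directory)
    labels_csv = Path(labels_csv) if labels_csv else directory / "labels.csv"
    df = read_labels(labels_csv)
    meshes = []
    for row in df.itertuples(index=False):
        m = load_mesh(directory / row.file)
        m.label = row.label16
        meshes.append(m)
    return meshes, df
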