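import numpy as np
import pytest

from toothseq import (
    SyntheticDatasetConfig,
    TriMesh,
    class_specs_16,
    decimate_mesh,
    generate_dataset,
    generate_tooth,
)


def random_valid_mesh(rng: np.random.Generator, n_vertices: int = 12, n_faces: int = 8) -> TriMesh:
    """A random mesh satisfying the TriMesh invariants (not necessarily
    manifold). Every vertex is referenced by some face and vertices are
    numbered in order of first reference, so the mesh survives formats that
    store geometry per facet (STL)."""
    assert 3 * n_faces >= n_vertices
    vertices = rng.normal(size=(n_vertices, 3)) * 10.0
    perm = rng.permutation(n_vertices)
    faces = [perm[i : i + 3] for i in range(0, n_vertices - 2, 3)]
    if n_vertices % 3:
        faces.append(np.concatenate([perm[-(n_vertices % 3) :], perm[: 3 - n_vertices % 3]]))
    while len(faces) < n_faces:
        faces.append(rng.choice(n_vertices, size=3, replace=False))
    faces = np.array(faces[:n_faces])
    # renumber vertices by first appearance in the face stream
    order = []
    seen = set()
    for idx in faces.ravel():
        if idx not in seen:
            seen.add(idx)
            order.append(idx)
    order = np.array(order)
    rank = np.empty(n_vertices, dtype=int)
    rank[order] = np.arange(n_vertices)
    return TriMesh(vertices[order], rank[faces]).validate()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def molar_spec():
    return next(s for s in class_specs_16() if s.class_name == "1st Molar (L)")


@pytest.fixture(scope="session")
def incisor_spec():
    return next(s for s in class_specs_16() if s.class_name == "Central Incisor (L)")


@pytest.fixture(scope="session")
def small_bank():
    """One subject's 16 teeth at low density, decimated to 60 faces."""
    meshes, labels = generate_dataset(
        SyntheticDatasetConfig(n_subjects=1, dense_faces=320, seed=11)
    )
    return [decimate_mesh(m, 60) for m in meshes], labels


@pytest.fixture(scope="session")
def decimated_900():
    """A dense synthetic molar decimated to the standard 900-triangle budget."""
    spec = next(s for s in class_specs_16() if s.class_name == "1st Molar (L)")
    dense = generate_tooth(spec, seed=5, dense_faces=5120)
    return decimate_mesh(dense, 900)
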