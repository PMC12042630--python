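"""Mesh container, format round-trips, and fixed-budget decimation."""

import numpy as np
import pytest
import trimesh as _trimesh
from scipy.spatial import cKDTree

from toothseq import (
    MeshValidationError,
    TriMesh,
    decimate_mesh,
    generate_tooth,
    load_mesh,
    save_mesh,
)
from conftest import random_valid_mesh


class TestValidation:
    def test_minimal_obj(self, tmp_path):
        p = tmp_path / "tri.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        m = load_mesh(p)
        assert m.n_vertices == 3 and m.n_faces == 1

    def test_quad_cube_triangulates_to_12(self, tmp_path):
        box = _trimesh.creation.box()
        p = tmp_path / "cube.ply"
        box.export(p)
        assert load_mesh(p).n_faces == 12

    def test_face_index_out_of_range_is_validation_error(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 5\n")
        with pytest.raises(MeshValidationError, match="out of"):
            load_mesh(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            load_mesh(tmp_path / "nope.obj")

    @pytest.mark.parametrize(
        "verts,faces,msg",
        [
            (np.zeros((3, 3)), np.empty((0, 3), int), "at least 1 face"),
            (np.zeros((2, 3)), [[0, 1, 0]], "at least 3"),
            ([[0, 0, np.nan], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]], "NaN"),
            (np.eye(3), [[0, 1, 1]], "repeats"),
        ],
    )
    def test_invariant_violations(self, verts, faces, msg):
        with pytest.raises(MeshValidationError, match=msg):
            TriMesh(np.asarray(verts, float), np.asarray(faces, int)).validate()

    def test_save_refuses_invalid_mesh_before_write(self, tmp_path):
        bad = TriMesh(np.zeros((3, 3)), np.empty((0, 3), dtype=int))
        target = tmp_path / "out.obj"
        with pytest.raises(MeshValidationError):
            save_mesh(bad, target)
        assert not target.exists()


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["obj", "stl", "ply"])
    def test_random_mesh_round_trip(self, fmt, rng, tmp_path):
        m = random_valid_mesh(rng)
        p = tmp_path / f"m.{fmt}"
        save_mesh(m, p)
        back = load_mesh(p)
        assert np.allclose(back.vertices, m.vertices, atol=1e-6)
        if fmt == "stl":
            # STL re-welds; topology must match up to the weld
            assert back.n_faces == m.n_faces
        else:
            assert np.array_equal(back.faces, m.faces)

    def test_single_triangle_obj_records(self, tmp_path):
        m = TriMesh(np.eye(3), np.array([[0, 1, 2]]))
        p = tmp_path / "t.obj"
        save_mesh(m, p)
        lines = [l.split()[0] for l in p.read_text().splitlines() if l.strip()]
        assert lines.count("v") == 3 and lines.count("f") == 1

    def test_stl_weld_restores_shared_vertices(self, tmp_path):
        box = _trimesh.creation.box()
        m = TriMesh(np.asarray(box.vertices), np.asarray(box.faces))
        p = tmp_path / "cube.stl"
        save_mesh(m, p)
        back = load_mesh(p)
        assert back.n_vertices == 8 and back.n_faces == 12

    def test_decimated_mesh_round_trips(self, decimated_900, tmp_path):
        p = tmp_path / "d.ply"
        save_mesh(decimated_900, p)
        back = load_mesh(p)
        assert back.n_faces == 900
        assert np.allclose(back.vertices, decimated_900.vertices, atol=1e-6)


class TestDecimation:
    def test_exact_face_count_and_metadata(self):
        from toothseq import class_specs_16

        spec_mesh = generate_tooth(class_specs_16()[3], seed=2, dense_faces=1280)
        spec_mesh.label = "1st Premolar (L)"
        spec_mesh.source_id = "probe"
        out = decimate_mesh(spec_mesh, 240)
        assert out.n_faces == 240
        assert out.label == "1st Premolar (L)" and out.source_id == "probe"
        out.validate()  # no NaNs, no degenerate faces

    def test_identity_short_circuit(self, small_bank):
        m = small_bank[0][0]
        out = decimate_mesh(m, m.n_faces)
        assert np.array_equal(out.faces, m.faces)
        assert np.array_equal(out.vertices, m.vertices)

    def test_deterministic(self, molar_spec):
        m = generate_tooth(molar_spec, seed=9, dense_faces=1280)
        a = decimate_mesh(m, 300)
        b = decimate_mesh(m, 300)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_below_target_behaviour(self, small_bank):
        m = small_bank[0][0]  # 60 faces
        with pytest.raises(ValueError, match="subdivide"):
            decimate_mesh(m, 100)
        assert decimate_mesh(m, 100, on_deficit="pass").n_faces == 60
        up = decimate_mesh(m, 100, on_deficit="split")
        assert up.n_faces == 100
        up.validate()

    def test_icosphere_surface_deviation_below_1pct(self):
        """Decimating a depth-5 icosphere to 900 faces moves sampled surface
        points by less than 1% of the bounding-box diagonal."""
        ico = _trimesh.creation.icosphere(subdivisions=5)
        m = TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        d = decimate_mesh(m, 900)
        assert d.n_faces == 900
        sampled, _ = _trimesh.sample.sample_surface(
            _trimesh.Trimesh(d.vertices, d.faces, process=False), 10000, seed=0
        )
        reference, _ = _trimesh.sample.sample_surface(ico, 200000, seed=0)
        dist, _ = cKDTree(reference).query(sampled)
        assert dist.mean() < 0.01 * m.bbox_diagonal()
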