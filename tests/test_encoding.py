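"""Feature extraction and grayscale-image encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from toothseq import (
    FeatureMatrix,
    TriMesh,
    extract_features,
    read_image,
    to_feature_image,
    write_image,
)
from conftest import random_valid_mesh


def _triangle_mesh():
    return TriMesh(
        np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]), np.array([[0, 1, 2]])
    )


class TestExtractFeatures:
    def test_single_triangle_row(self):
        fm = extract_features(_triangle_mesh(), subset="both")
        expected = [0, 0, 0, 1, 0, 0, 0, 1, 0, 1 / 3, 1 / 3, 0]
        assert np.allclose(fm.values, [expected])

    def test_centroid_columns_are_vertex_means(self, rng):
        m = random_valid_mesh(rng, n_vertices=30, n_faces=40)
        fm = extract_features(m, subset="both")
        verts = fm.values[:, :9].reshape(-1, 3, 3)
        assert np.abs(verts.mean(axis=1) - fm.values[:, 9:]).max() < 1e-9

    def test_subset_shapes_and_slices(self, decimated_900):
        both = extract_features(decimated_900, subset="both").values
        vertices = extract_features(decimated_900, subset="vertices").values
        centers = extract_features(decimated_900, subset="centers").values
        assert both.shape == (900, 12)
        assert vertices.shape == (900, 9) and np.array_equal(vertices, both[:, :9])
        assert centers.shape == (900, 3) and np.array_equal(centers, both[:, 9:])

    def test_permutation_covariance(self, rng):
        m = random_valid_mesh(rng, n_vertices=15, n_faces=12)
        perm = rng.permutation(12)
        permuted = TriMesh(m.vertices.copy(), m.faces[perm])
        a = extract_features(m).values
        b = extract_features(permuted).values
        assert np.array_equal(a[perm], b)

    def test_strict_count_mismatch_names_counts(self, rng):
        m = random_valid_mesh(rng, n_faces=8)
        with pytest.raises(ValueError, match="8.*10"):
            extract_features(m, expected_faces=10)

    def test_lenient_pads_and_truncates(self, rng):
        m = random_valid_mesh(rng, n_faces=8)
        padded = extract_features(m, expected_faces=10, strict=False).values
        assert padded.shape == (10, 12) and np.all(padded[8:] == 0)
        cut = extract_features(m, expected_faces=5, strict=False).values
        assert cut.shape == (5, 12)

    def test_unknown_subset(self, rng):
        with pytest.raises(ValueError, match="subset"):
            extract_features(random_valid_mesh(rng), subset="normals")


class TestFeatureImage:
    def test_minmax_arithmetic(self):
        fm = FeatureMatrix(np.array([[0.0, 5.0, 10.0]] * 2)[:, :3])
        img = to_feature_image(fm)
        assert np.allclose(sorted(set(img.pixels.ravel())), [0.0, 0.5, 1.0])

    def test_constant_matrix_maps_to_zeros(self):
        img = to_feature_image(FeatureMatrix(np.full((4, 3), 7.0)))
        assert np.all(img.pixels == 0.0)

    def test_quantized_mode_hits_0_and_255(self, rng):
        fm = FeatureMatrix(rng.normal(size=(20, 12)))
        img = to_feature_image(fm, quantize_8bit=True)
        assert img.pixels.dtype == np.uint8
        assert img.pixels.min() == 0 and img.pixels.max() == 255

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            to_feature_image(FeatureMatrix(np.array([[np.inf, 0, 0]])))

    @settings(derandomize=True, max_examples=50)
    @given(
        arrays(
            np.float64,
            (6, 12),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
        )
    )
    def test_float_mode_is_invertible(self, values):
        img = to_feature_image(FeatureMatrix(values))
        assert np.abs(img.invert() - values).max() < 1e-9 * max(
            1.0, np.abs(values).max()
        )

    def test_normalized_range(self, rng):
        img = to_feature_image(FeatureMatrix(rng.normal(size=(9, 12))))
        assert img.pixels.min() == 0.0 and img.pixels.max() == 1.0


class TestImageIO:
    def test_float_round_trip(self, rng, tmp_path):
        img = to_feature_image(FeatureMatrix(rng.normal(size=(30, 12))))
        p = tmp_path / "img.npz"
        write_image(img, p)
        back = read_image(p)
        assert np.abs(back.pixels - img.pixels).max() < 1e-7
        assert back.norm_lo == img.norm_lo and back.norm_hi == img.norm_hi

    def test_png_round_trip_identical(self, rng, tmp_path):
        img = to_feature_image(FeatureMatrix(rng.normal(size=(30, 12))), quantize_8bit=True)
        p = tmp_path / "img.png"
        write_image(img, p)
        back = read_image(p)
        assert np.array_equal(back.pixels, img.pixels)
        assert back.norm_lo == pytest.approx(img.norm_lo)

    def test_budget_image_dimensions(self, decimated_900, tmp_path):
        img = to_feature_image(extract_features(decimated_900))
        p = tmp_path / "img.npz"
        write_image(img, p)
        assert read_image(p).shape == (900, 12)

    def test_corrupt_file(self, tmp_path):
        p = tmp_path / "junk.npz"
        p.write_bytes(b"not an archive")
        with pytest.raises(IOError):
            read_image(p)
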