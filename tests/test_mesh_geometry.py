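"""Geometry: primitive surfaces, Laplacian, geodesics, phantom validity, I/O."""

import numpy as np
import pytest

from ecgi.mesh_geometry import (
    InvalidGeometryError,
    TriSurface,
    contains_points,
    cotangent_weights,
    farthest_point_sample,
    geodesic_distances,
    is_refinement_of,
    make_sphere,
    make_torso_phantom,
    make_ventricle,
    read_surface,
    subdivide,
    surface_laplacian,
    write_surface,
)


@pytest.mark.parametrize(
    "refinement, n_vertices, n_faces",
    [(0, 12, 20), (1, 42, 80), (2, 162, 320)],
)
def test_icosphere_counts(refinement, n_vertices, n_faces):
    s = make_sphere(1.0, refinement)
    assert (s.n_vertices, s.n_faces) == (n_vertices, n_faces)
    s.validate()


def test_icosphere_area_converges_to_closed_form():
    r = 2.0
    s = make_sphere(r, 3)
    assert abs(s.total_area() - 4 * np.pi * r**2) / (4 * np.pi * r**2) < 0.01


def test_sphere_rejects_bad_arguments():
    with pytest.raises(ValueError):
        make_sphere(-1.0, 2)
    with pytest.raises(ValueError):
        make_sphere(1.0, -1)


class TestVentricle:
    def test_closed_manifold_and_volume(self):
        v = make_ventricle()
        v.validate()
        a, b, c = 0.033, 0.033, 0.055
        w = 0.010
        shell = 2.0 / 3.0 * np.pi * (a * b * c - (a - w) * (b - w) * (c - w))
        assert abs(v.signed_volume() - shell) / shell < 0.02

    def test_labels_partition(self):
        v = make_ventricle(target_vertices=400)
        assert set(v.labels) == {"epicardial", "endocardial", "basal"}
        assert len(v.labels) == v.n_vertices

    def test_wall_too_thick_raises(self):
        with pytest.raises(InvalidGeometryError):
            make_ventricle(outer_semi_axes=(0.03, 0.03, 0.05), wall_thickness=0.03)


def test_vertex_areas_sum_to_total_area():
    s = make_sphere(0.1, 2)
    assert np.isclose(s.vertex_areas().sum(), s.total_area(), rtol=1e-10)


class TestLaplacian:
    def test_constant_in_null_space(self):
        s = make_sphere(1.0, 2)
        L = surface_laplacian(s)
        assert np.abs(L @ np.ones(s.n_vertices)).max() < 1e-12

    def test_weight_matrix_symmetric(self):
        s = make_ventricle(target_vertices=200)
        W = cotangent_weights(s)
        assert abs(W - W.T).max() < 1e-12

    def test_flat_patch_values(self):
        # structured triangulated square; interior Laplacian of x^2+y^2 is 4
        # and of a linear function is 0 (cotangent weights need no closedness)
        n = 15
        xs = np.linspace(-1, 1, n)
        X, Y = np.meshgrid(xs, xs)
        verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(n * n)])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces += [(a, a + 1, a + n), (a + 1, a + n + 1, a + n)]
        surf = TriSurface(verts, np.asarray(faces))
        W = cotangent_weights(surf)
        areas = surf.vertex_areas()
        interior = np.array(
            [i * n + j for i in range(3, n - 3) for j in range(3, n - 3)]
        )

        f_lin = 2.0 * verts[:, 0] - 3.0 * verts[:, 1]
        lap_lin = (W @ f_lin - np.asarray(W.sum(axis=1)).ravel() * f_lin) / areas
        assert np.abs(lap_lin[interior]).max() < 1e-9

        f_quad = verts[:, 0] ** 2 + verts[:, 1] ** 2
        lap_quad = (W @ f_quad - np.asarray(W.sum(axis=1)).ravel() * f_quad) / areas
        assert np.allclose(lap_quad[interior], 4.0, rtol=1e-6)

    def test_open_surface_rejected(self):
        s = make_sphere(1.0, 1)
        open_surf = TriSurface(s.vertices, s.faces[:-1])
        with pytest.raises(InvalidGeometryError):
            surface_laplacian(open_surf)


class TestGeodesics:
    def test_sources_have_zero_distance(self):
        s = make_sphere(1.0, 2)
        d = geodesic_distances(s, np.arange(s.n_vertices))
        assert np.all(d == 0)

    def test_antipodal_matches_great_circle(self):
        r = 2.0
        s = make_sphere(r, 3)
        d = geodesic_distances(s, [0])
        anti = int(np.argmin(np.linalg.norm(s.vertices + s.vertices[0], axis=1)))
        assert abs(d[anti] - np.pi * r) / (np.pi * r) < 0.05

    def test_adding_source_never_increases_distance(self):
        s = make_sphere(1.0, 2)
        d1 = geodesic_distances(s, [0])
        d2 = geodesic_distances(s, [0, 50])
        assert np.all(d2 <= d1 + 1e-12)

    def test_transmural_links_shorten_wall_crossing(self):
        v = make_ventricle(target_vertices=300)
        endo = int(np.nonzero(v.labels == "endocardial")[0][0])
        d_surf = geodesic_distances(v, [endo])
        d_wall = geodesic_distances(v, [endo], transmural=True)
        epi = v.labels == "epicardial"
        assert d_wall[epi].max() < d_surf[epi].max()


class TestPhantom:
    def test_default_phantom_valid(self, small_phantom):
        small_phantom.validate()
        assert set(small_phantom.surfaces) == {
            "torso", "lung_left", "lung_right", "heart", "blood",
        }

    def test_electrode_count_follows_config(self, small_phantom):
        assert len(small_phantom.electrodes) == 40

    def test_degenerate_config_rejected(self):
        with pytest.raises(InvalidGeometryError):
            make_torso_phantom({"lung_left": {"center": [0.5, 0.0, 0.0]}})

    def test_winding_number_containment(self):
        s = make_sphere(1.0, 2)
        pts = np.array([[0.0, 0.0, 0.0], [0.5, 0.2, -0.3], [1.5, 0.0, 0.0]])
        assert list(contains_points(s, pts)) == [True, True, False]


def test_farthest_point_sampling_deterministic_and_spread(rng):
    pts = rng.normal(size=(300, 3))
    idx1 = farthest_point_sample(pts, 25)
    idx2 = farthest_point_sample(pts, 25)
    assert np.array_equal(idx1, idx2)
    assert len(set(idx1.tolist())) == 25


def test_subdivision_is_refinement_with_labels():
    v = make_ventricle(target_vertices=200)
    f = subdivide(v)
    assert is_refinement_of(f, v)
    assert f.n_faces == 4 * v.n_faces
    assert set(f.labels) == set(v.labels)
    # parent labels are preserved on the leading vertex block
    assert list(f.labels[: v.n_vertices]) == list(v.labels)


@pytest.mark.parametrize("ext", ["ply", "off"])
def test_surface_io_roundtrip(tmp_path, ext):
    v = make_ventricle(target_vertices=200)
    path = tmp_path / f"cup.{ext}"
    write_surface(path, v)
    back = read_surface(path)
    assert np.allclose(back.vertices, v.vertices, atol=1e-8)
    assert np.array_equal(back.faces, v.faces)
    if ext == "ply":
        assert list(back.labels) == list(v.labels)
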