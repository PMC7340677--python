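"""Volume conductor: solid angles, presets, transfer matrix, sphere oracle."""

import numpy as np
import pytest

from ecgi.mesh_geometry import make_sphere
from ecgi.volume_conductor import (
    CONDUCTIVITY_PRESETS,
    ConductivitySet,
    analytic_dipole_sphere,
    assemble_bem,
    dipole_infinite_medium,
    solid_angles,
    sphere_dipole_bem,
    transfer_matrix,
)


class TestSolidAngles:
    def test_gauss_identities(self):
        s = make_sphere(1.0, 2)
        tri = s.vertices[s.faces]
        inside = solid_angles(np.array([[0.1, -0.2, 0.05]]), tri).sum()
        outside = solid_angles(np.array([[2.5, 0.0, 0.0]]), tri).sum()
        assert abs(inside - 4 * np.pi) < 1e-9
        assert abs(outside) < 1e-9

    def test_vertex_sees_interior_angle(self):
        s = make_sphere(1.0, 2)
        tri = s.vertices[s.faces]
        om = solid_angles(s.vertices[:5], tri).sum(axis=1)
        # interior angle at a nearly flat vertex is a bit below 2*pi
        assert np.all(om > 0.7 * 2 * np.pi)
        assert np.all(om < 2 * np.pi)


class TestConductivityPresets:
    def test_table_values(self):
        # the five conductivity sets used to build the transfer matrices
        expect = {
            "A": (0.2, 0.04, 0.6, 0.2),
            "A1": (0.2, 0.06, 0.6, 0.1),
            "A2": (0.2, 0.06, 0.6, 0.4),
            "A3": (0.2, 0.01, 0.6, 0.2),
            "A4": (0.2, 0.06, 0.75, 0.3),
        }
        for name, (th, lu, bl, he) in expect.items():
            c = CONDUCTIVITY_PRESETS[name]
            assert (c.thorax, c.lungs, c.blood, c.heart) == (th, lu, bl, he)

    def test_positive_required(self):
        with pytest.raises(ValueError):
            ConductivitySet(thorax=0.2, lungs=-0.1, blood=0.6, heart=0.2)


class TestSphereOracle:
    def test_central_dipole_closed_form(self):
        R, sig = 0.1, 0.2
        s = make_sphere(R, 2)
        p = np.array([0.0, 0.0, 1e-6])
        pot = analytic_dipole_sphere(p, np.zeros(3), R, sig, s.vertices, lmax=12)
        closed = 3.0 * (s.vertices @ p) / (4 * np.pi * sig * R**3)
        closed -= closed.mean()
        assert np.allclose(pot, closed, rtol=1e-10, atol=1e-12)

    def test_reflection_symmetry(self):
        R, sig = 0.1, 0.2
        s = make_sphere(R, 2)
        p = np.array([0.0, 0.0, 2e-6])
        r0 = np.array([0.02, 0.0, 0.03])
        mirror = np.diag([1.0, 1.0, -1.0])
        pot = analytic_dipole_sphere(p, r0, R, sig, s.vertices, lmax=24)
        pot_m = analytic_dipole_sphere(mirror @ p, mirror @ r0, R, sig, s.vertices @ mirror, lmax=24)
        assert np.allclose(pot, pot_m, rtol=1e-8, atol=1e-12)

    def test_zero_mean_and_position_validation(self):
        R = 0.1
        s = make_sphere(R, 1)
        pot = analytic_dipole_sphere([0, 0, 1e-6], [0, 0, 0.04], R, 0.2, s.vertices, lmax=16)
        assert abs(pot.mean()) < 1e-15 * np.abs(pot).max() + 1e-30
        with pytest.raises(ValueError):
            analytic_dipole_sphere([0, 0, 1e-6], [0, 0, 0.2], R, 0.2, s.vertices)

    def test_bem_matches_oracle_on_coarse_sphere(self):
        # the tighter 2000-face check with a refinement study lives in the
        # acceptance suite; here a quick coarse-mesh guard
        R, sig = 0.1, 0.2
        s = make_sphere(R, 2)
        p = np.array([0.0, 0.0, 1e-6])
        r0 = np.array([0.0, 0.0, 0.04])
        v = sphere_dipole_bem(s, p, r0, sig)
        v_ref = analytic_dipole_sphere(p, r0, R, sig, s.vertices, lmax=24)
        err = np.linalg.norm(v - v_ref) / np.linalg.norm(v_ref)
        assert err < 0.05


@pytest.fixture(scope="module")
def geometry(small_phantom):
    return assemble_bem(small_phantom)


class TestTransferMatrix:
    def test_closed_layer_null(self, geometry):
        tm = transfer_matrix(geometry, "A")
        null = np.abs(tm.A @ np.ones(tm.n_sources)).max()
        column_scale = np.abs(tm.A).max(axis=0).mean()
        assert null < 1e-8 * column_scale

    def test_linearity_and_conductivity_scaling(self, geometry, rng):
        tm = transfer_matrix(geometry, "A")
        tm2 = transfer_matrix(geometry, CONDUCTIVITY_PRESETS["A"].scaled(2.0))
        assert np.allclose(tm2.A, tm.A / 2.0, rtol=1e-9)
        m = rng.normal(size=tm.n_sources)
        assert np.allclose(tm.A @ (2 * m), 2 * (tm.A @ m))

    def test_all_presets_finite_and_null(self, geometry):
        for name in CONDUCTIVITY_PRESETS:
            tm = transfer_matrix(geometry, name)
            assert np.all(np.isfinite(tm.A))
            null = np.abs(tm.A @ np.ones(tm.n_sources)).max()
            assert null < 1e-8 * np.abs(tm.A).max(axis=0).mean()


def test_infinite_medium_dipole_decays_as_r_squared():
    p = np.array([0.0, 0.0, 1.0])
    pts = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 2.0]])
    v = dipole_infinite_medium(p, np.zeros(3), 1.0, pts)
    assert v[0] / v[1] == pytest.approx(4.0)
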