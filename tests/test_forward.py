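"""Forward-model physics: radial silence, linearity, closed-form oracles,
rigid perturbations and geometry I/O."""

import math

import numpy as np
import pytest

from megloc.forward import (
    Dipole,
    HeadPerturbation,
    PrecomputedLeadField,
    SensorArray,
    SphereModel,
    dipole_field,
    helmet_array,
    lead_field,
    lead_field_grid,
    mixing_matrix,
    perturb_geometry,
    read_sensor_table,
)

MU0_4PI = 1e-7


def radial_biot_savart(q, p, r_pos, center):
    """Independent oracle: radial field component from the primary current only.

    For a spherical conductor the volume currents contribute nothing to the
    radial field component, so B_r = mu0/4pi * (q x (r-p)) . r_hat / |r-p|^3.
    """
    r = np.asarray(r_pos) - center
    pp = np.asarray(p) - center
    d = r - pp
    return MU0_4PI * np.dot(np.cross(q, d), r / np.linalg.norm(r)) / np.linalg.norm(d) ** 3


def scalar_sarvas(q, p, r_pos, orient, center):
    """Scalar (pure-math) dual implementation of the conductor-sphere field."""
    r = [r_pos[i] - center[i] for i in range(3)]
    p0 = [p[i] - center[i] for i in range(3)]
    a = [r[i] - p0[i] for i in range(3)]
    an = math.sqrt(sum(x * x for x in a))
    rn = math.sqrt(sum(x * x for x in r))
    ar = sum(a[i] * r[i] for i in range(3))
    p0r = sum(p0[i] * r[i] for i in range(3))
    F = an * (rn * an + rn * rn - p0r)
    c1 = an * an / rn + ar / an + 2 * an + 2 * rn
    c2 = an + 2 * rn + ar / an
    gF = [c1 * r[i] - c2 * p0[i] for i in range(3)]
    qxp = [
        q[1] * p0[2] - q[2] * p0[1],
        q[2] * p0[0] - q[0] * p0[2],
        q[0] * p0[1] - q[1] * p0[0],
    ]
    rq = sum(r[i] * qxp[i] for i in range(3))
    B = [MU0_4PI / F**2 * (F * qxp[i] - rq * gF[i]) for i in range(3)]
    return sum(B[i] * orient[i] for i in range(3))


def random_interior_points(rng, n, radius, lo=0.01, hi=0.95):
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * (rng.uniform(lo, hi, size=(n, 1)) * radius)


class TestDipoleField:
    def test_radial_dipole_is_silent(self, sphere, toy_sensors, rng):
        for p in random_interior_points(rng, 50, sphere.radius):
            q_rad = p / np.linalg.norm(p) * 1e-8
            f = dipole_field(Dipole(p, q_rad), toy_sensors, sphere)
            q_tan = np.cross(p, [0.0, 0.0, 1.0])
            q_tan = q_tan / np.linalg.norm(q_tan) * 1e-8
            f_tan = dipole_field(Dipole(p, q_tan), toy_sensors, sphere)
            assert np.linalg.norm(f) < 1e-10 * np.linalg.norm(f_tan)

    def test_linearity_and_superposition(self, sphere, toy_sensors, rng):
        p = np.array([0.03, -0.02, 0.04])
        q1, q2 = rng.standard_normal(3) * 1e-8, rng.standard_normal(3) * 1e-8
        f1 = dipole_field(Dipole(p, q1), toy_sensors, sphere)
        f2 = dipole_field(Dipole(p, q2), toy_sensors, sphere)
        f12 = dipole_field(Dipole(p, q1 + q2), toy_sensors, sphere)
        np.testing.assert_allclose(f12, f1 + f2, rtol=1e-12, atol=1e-15 * np.abs(f1).max())
        np.testing.assert_allclose(
            dipole_field(Dipole(p, 2 * q1), toy_sensors, sphere), 2 * f1, rtol=1e-14
        )

    def test_radial_sensor_biot_savart_oracle(self, sphere, sensors, rng):
        for p in random_interior_points(rng, 20, sphere.radius):
            q = np.cross(p, rng.standard_normal(3))
            q = q / np.linalg.norm(q) * 1e-8
            f = dipole_field(Dipole(p, q), sensors, sphere)
            for j in (0, 101, 305):
                expect = radial_biot_savart(q, p, sensors.positions[j], sphere.center)
                assert abs(f[j] - expect) <= 1e-10 * abs(expect)

    def test_center_and_exterior_locations_rejected(self, sphere, toy_sensors):
        with pytest.raises(ValueError, match="center"):
            dipole_field(Dipole(np.zeros(3), np.ones(3)), toy_sensors, sphere)
        with pytest.raises(ValueError, match="outside"):
            dipole_field(Dipole(np.array([0.2, 0.0, 0.0]), np.ones(3)), toy_sensors, sphere)

    def test_sensor_inside_conductor_rejected(self, sphere):
        bad = SensorArray(positions=[[0.01, 0.0, 0.0]], orientations=[[1.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="inside"):
            dipole_field(Dipole(np.array([0.0, 0.0, 0.03]), np.ones(3)), bad, sphere)


class TestLeadField:
    def test_lead_field_times_moment_equals_dipole_field(self, sphere, toy_sensors, rng):
        p = np.array([0.02, 0.03, -0.01])
        L = lead_field(p, toy_sensors, sphere)
        for _ in range(5):
            q = rng.standard_normal(3)
            np.testing.assert_allclose(
                L @ q, dipole_field(Dipole(p, q), toy_sensors, sphere), rtol=1e-12
            )

    def test_radial_column_vanishes_on_z_axis(self, sphere, toy_sensors):
        L = lead_field(np.array([0.0, 0.0, 0.05]), toy_sensors, sphere)
        assert np.abs(L[:, 2]).max() < 1e-12 * np.abs(L).max()

    def test_scalar_dual_implementation(self, sphere, rng):
        two = SensorArray(
            positions=[[0.0, 0.0, 0.12], [0.08, 0.05, 0.09]],
            orientations=[[0.0, 0.0, 1.0], [0.6, 0.0, 0.8]],
        )
        p = np.array([0.025, -0.015, 0.04])
        L = lead_field(p, two, sphere)
        for j in range(2):
            for k, e in enumerate(np.eye(3)):
                expect = scalar_sarvas(
                    e, p, two.positions[j], two.orientations[j], sphere.center
                )
                assert abs(L[j, k] - expect) <= 1e-10 * max(abs(expect), 1e-30)

    def test_grid_matches_single_point_evaluation(self, sphere, toy_sensors, rng):
        pts = random_interior_points(rng, 8, sphere.radius)
        G = lead_field_grid(pts, toy_sensors, sphere)
        for i, p in enumerate(pts):
            np.testing.assert_allclose(G[i], lead_field(p, toy_sensors, sphere), rtol=1e-12)


class TestMixingMatrix:
    def test_single_source_is_topography_column(self, sphere, toy_sensors):
        p = np.array([[0.01, 0.02, 0.05]])
        o = np.array([[0.0, 1.0, 0.0]])
        A = mixing_matrix(p, o, toy_sensors, sphere)
        np.testing.assert_allclose(A[:, 0], lead_field(p[0], toy_sensors, sphere) @ o[0])

    def test_row_permutation_permutes_columns(self, sphere, toy_sensors, rng):
        P = random_interior_points(rng, 3, sphere.radius)
        O = rng.standard_normal((3, 3))
        O /= np.linalg.norm(O, axis=1, keepdims=True)
        A = mixing_matrix(P, O, toy_sensors, sphere)
        perm = [2, 0, 1]
        A2 = mixing_matrix(P[perm], O[perm], toy_sensors, sphere)
        np.testing.assert_allclose(A2, A[:, perm], rtol=1e-14)

    def test_distinct_sources_give_full_rank(self, sphere, sensors):
        P = np.array([[0.03, 0.0, 0.04], [-0.02, 0.04, 0.02]])
        O = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        A = mixing_matrix(P, O, sensors, sphere)
        assert np.linalg.matrix_rank(A) == 2


class TestPerturbation:
    def test_identity_is_noop(self, toy_space, sphere):
        out = perturb_geometry(toy_space.points, HeadPerturbation(), sphere)
        assert np.abs(out - toy_space.points).max() == 0.0

    def test_translation_is_rigid(self, toy_space, sphere):
        pert = HeadPerturbation(translation_mm=np.array([3.0, 0.0, 0.0]))
        out = perturb_geometry(toy_space.points, pert, sphere)
        moved = np.linalg.norm(out - toy_space.points, axis=1)
        np.testing.assert_allclose(moved, 3e-3, rtol=1e-12)
        d0 = np.linalg.norm(toy_space.points[:50, None] - toy_space.points[None, :50], axis=2)
        d1 = np.linalg.norm(out[:50, None] - out[None, :50], axis=2)
        np.testing.assert_allclose(d1, d0, atol=1e-12 * sphere.radius)

    def test_rotation_chord_length(self, sphere):
        p = np.array([[0.07, 0.0, 0.0]])
        pert = HeadPerturbation(rotation_axis="z", rotation_angle_deg=1.0)
        out = perturb_geometry(p, pert, sphere)
        chord = 2 * 0.07 * np.sin(np.deg2rad(0.5))
        assert np.isclose(np.linalg.norm(out - p), chord, rtol=1e-10)

    def test_point_leaving_sphere_reports_indices(self, sphere):
        p = np.array([[0.088, 0.0, 0.0], [0.0, 0.0, 0.01]])
        pert = HeadPerturbation(translation_mm=np.array([5.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match=r"\[0\]"):
            perturb_geometry(p, pert, sphere)


class TestGeometryIO:
    def test_sensor_table_roundtrip(self, tmp_path):
        text = (
            "# synthetic two-sensor table\n"
            "A1 0.0 0.0 0.12  0 0 1\n"
            "A2, 0.08, 0.05, 0.09, 0.6, 0.0, 0.8\n"
        )
        path = tmp_path / "sensors.txt"
        path.write_text(text)
        arr = read_sensor_table(path)
        assert arr.labels == ("A1", "A2")
        np.testing.assert_allclose(arr.positions[1], [0.08, 0.05, 0.09])

    def test_sensor_table_bad_row(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("A1 0 0 0.12 0 0\n")
        with pytest.raises(ValueError, match="7 fields"):
            read_sensor_table(path)

    def test_precomputed_lead_field_roundtrip(self, tmp_path, sphere, toy_sensors, rng):
        pts = random_interior_points(rng, 5, sphere.radius)
        G = lead_field_grid(pts, toy_sensors, sphere)
        prov = PrecomputedLeadField(points=pts, lead_fields=G)
        path = tmp_path / "lf.h5"
        prov.to_file(path)
        loaded = PrecomputedLeadField.from_file(path)
        np.testing.assert_array_equal(loaded(pts), G)
        with pytest.raises(KeyError, match="not in"):
            loaded(np.array([[0.0, 0.0, 0.011]]))


def test_helmet_geometry(sphere):
    arr = helmet_array(306, sphere)
    r = np.linalg.norm(arr.positions - sphere.center, axis=1)
    np.testing.assert_allclose(r, 1.25 * sphere.radius, rtol=1e-12)
    # radial magnetometers
    rad = (arr.positions - sphere.center) / r[:, None]
    np.testing.assert_allclose(arr.orientations, rad, atol=1e-12)
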