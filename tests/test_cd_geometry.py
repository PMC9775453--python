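"""Macrocycle conformational descriptors against constructed ground truth."""

import math

import numpy as np
import pytest

from conftest import random_rigid_transform, transform_structure
from cycloscope.cd_geometry import (
    cd_axis,
    classify_rotamer,
    fit_mean_plane,
    host_puckers,
    o4_polygon_metrics,
    rim_states,
    ring_pucker,
    tilt_angle,
    tilt_angles,
    torsion,
)
from cycloscope.structure_io import annotate_cd
from cycloscope.synthetic_data import CDBuildSpec, build_ideal_cd


def brute_force_plane(points):
    """Oracle: refined grid search over unit normals for the least-squares plane."""
    pts = np.asarray(points)
    centered = pts - pts.mean(axis=0)

    def ssq(n):
        return float(((centered @ n) ** 2).sum())

    # coarse golden-spiral pass, then local cone refinement
    golden = math.pi * (3 - math.sqrt(5))
    m = 2000
    best = None
    for k in range(m):
        z = 1 - 2 * (k + 0.5) / m
        r = math.sqrt(max(0.0, 1 - z * z))
        n = np.array([r * math.cos(k * golden), r * math.sin(k * golden), z])
        if best is None or ssq(n) < ssq(best):
            best = n
    width = 0.1
    rng = np.random.default_rng(0)
    for _ in range(8):
        for _ in range(200):
            cand = best + width * rng.normal(size=3)
            cand /= np.linalg.norm(cand)
            if ssq(cand) < ssq(best):
                best = cand
        width /= 4.0
    return best


class TestPlaneFit:
    def test_coplanar_points_have_zero_deviation(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-5, 5, (7, 2)), np.zeros(7)])
        fit = fit_mean_plane(pts)
        assert fit.rms_dev == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.abs(fit.normal), [0, 0, 1], atol=1e-12)

    def test_alternating_heptagon_near_tenth_angstrom(self):
        ang = 2 * np.pi * np.arange(7) / 7
        z = 0.1 * (-1.0) ** np.arange(7)
        pts = np.column_stack([5 * np.cos(ang), 5 * np.sin(ang), z])
        fit = fit_mean_plane(pts)
        assert fit.rms_dev == pytest.approx(0.1, abs=0.005)
        assert abs(fit.normal[2]) > 0.999

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.normal(scale=3.0, size=(7, 3)) * np.array([1, 1, 0.15])
            fit = fit_mean_plane(pts)
            oracle = brute_force_plane(pts)
            angle = math.degrees(
                math.acos(min(1.0, abs(float(fit.normal @ oracle))))
            )
            assert angle < 0.01
            # and the SVD answer is never worse than the oracle's best
            centered = pts - pts.mean(axis=0)
            assert ((centered @ fit.normal) ** 2).sum() <= (
                (centered @ oracle) ** 2
            ).sum() + 1e-12

    def test_signed_deviations_sum_to_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.normal(size=(9, 3)) * np.array([4, 4, 0.5])
            fit = fit_mean_plane(pts)
            assert abs(fit.per_point_dev.sum()) < 1e-9

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_mean_plane(pts)


class TestPolygonMetrics:
    def test_regular_heptagon_closed_form(self, ideal_host):
        pm = o4_polygon_metrics(ideal_host)
        np.testing.assert_allclose(pm.d_K, 5.0, atol=1e-9)
        np.testing.assert_allclose(pm.d, 2 * 5.0 * math.sin(math.pi / 7), atol=1e-9)
        np.testing.assert_allclose(pm.dev, 0.0, atol=1e-9)
        assert pm.ellipticity == pytest.approx(1.0, abs=1e-12)

    def test_scaling_homogeneity(self, ideal_cd):
        st, _ = ideal_cd
        scaled = st.copy()
        scaled.set_coords(st.coords * 1.1)
        pm = o4_polygon_metrics(annotate_cd(scaled)[0])
        np.testing.assert_allclose(pm.d_K, 5.5, atol=1e-9)
        np.testing.assert_allclose(pm.d, 1.1 * 2 * 5.0 * math.sin(math.pi / 7), atol=1e-9)

    def test_elliptical_build_hits_requested_ratio(self):
        st, _ = build_ideal_cd(CDBuildSpec(o4_radius=5.0, ellipticity=1.2))
        pm = o4_polygon_metrics(annotate_cd(st)[0])
        assert pm.ellipticity == pytest.approx(1.2, abs=1e-9)

    def test_plane_noise_shows_up_in_dev(self):
        st, truth = build_ideal_cd(CDBuildSpec(plane_noise=0.15, seed=9))
        pm = o4_polygon_metrics(annotate_cd(st)[0])
        assert np.abs(pm.dev).max() > 0.01
        # deviations agree with an independent plane fit of the true O4 sites
        ref = fit_mean_plane(truth["o4_positions"]).per_point_dev
        np.testing.assert_allclose(np.abs(pm.dev), np.abs(ref), atol=1e-9)


class TestTiltAngles:
    def test_flat_build_has_zero_tilt(self, ideal_host):
        np.testing.assert_allclose(tilt_angles(ideal_host).tau, 0.0, atol=1e-6)

    @pytest.mark.parametrize("tilt", [-20.0, -10.0, 0.0, 10.0, 20.0, 40.0])
    def test_single_residue_recovery(self, tilt):
        tilts = [0.0] * 7
        tilts[3] = tilt
        st, _ = build_ideal_cd(CDBuildSpec(tilts=tuple(tilts)))
        host = annotate_cd(st)[0]
        assert tilt_angle(host, 3) == pytest.approx(tilt, abs=0.5)

    def test_uniform_tilt_recovery(self):
        st, _ = build_ideal_cd(CDBuildSpec(tilts=(15.0,) * 7))
        host = annotate_cd(st)[0]
        np.testing.assert_allclose(tilt_angles(host).tau, 15.0, atol=0.5)


class TestRotamers:
    @pytest.mark.parametrize(
        "omega,omega_prime,expected",
        [
            (-60.0, 60.0, "gg"),
            (60.0, 180.0, "gt"),
            (180.0, -60.0, "tg"),
            (-95.0, 25.0, "unclassified"),   # outside both ±30° windows
            (-60.0, 95.0, "unclassified"),
            (-89.9, 30.1, "gg"),              # inclusive boundary
        ],
    )
    def test_window_rule(self, omega, omega_prime, expected):
        assert classify_rotamer(omega, omega_prime) == expected

    @pytest.mark.parametrize("state", ["gg", "gt", "tg"])
    def test_builder_states_recovered(self, state):
        st, _ = build_ideal_cd(CDBuildSpec(rim_states=(state,) * 7))
        host = annotate_cd(st)[0]
        assert [r.state for r in rim_states(host)] == [state] * 7

    def test_mixed_states(self):
        states = ("gg", "gt", "gg", "tg", "gg", "gt", "gg")
        st, _ = build_ideal_cd(CDBuildSpec(rim_states=states))
        host = annotate_cd(st)[0]
        assert tuple(r.state for r in rim_states(host)) == states

    def test_torsion_matches_gemmi_oracle(self):
        import gemmi

        rng = np.random.default_rng(6)
        for _ in range(20):
            pts = rng.normal(scale=2.0, size=(4, 3))
            ours = torsion(*pts)
            oracle = math.degrees(
                gemmi.calculate_dihedral(*(gemmi.Position(*p) for p in pts))
            )
            assert ours == pytest.approx(oracle, abs=1e-9)


class TestPucker:
    def test_flat_hexagon_zero_amplitude(self):
        ang = np.pi / 3 * np.arange(6)
        ring = np.column_stack([1.45 * np.cos(ang), 1.45 * np.sin(ang), np.zeros(6)])
        res = ring_pucker(ring)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert not res.is_4C1

    def test_ideal_chair_near_pole(self):
        ang = np.pi / 3 * np.arange(6)
        z = 0.25 * (-1.0) ** (np.arange(6) + 1)
        ring = np.column_stack([1.361 * np.cos(ang), 1.361 * np.sin(ang), z])
        res = ring_pucker(ring)
        assert res.Q == pytest.approx(math.sqrt(6 * 0.25**2), abs=1e-9)
        assert res.theta < 5.0 or res.theta > 175.0
        # amplitude is invariant under ring inversion
        assert ring_pucker(ring * [1, 1, -1]).Q == pytest.approx(res.Q, abs=1e-12)

    def test_builder_residues_are_4c1(self, ideal_host):
        assert all(p.is_4C1 for p in host_puckers(ideal_host))

    def test_wrong_atom_count_rejected(self):
        with pytest.raises(ValueError):
            ring_pucker(np.zeros((5, 3)))


class TestAxis:
    def test_upright_build_axis_is_z(self, ideal_host):
        axis, anchor = cd_axis(ideal_host)
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(anchor, 0.0, atol=1e-9)

    def test_equivariance_under_rotation(self, ideal_cd):
        st, _ = ideal_cd
        rot = np.array(
            [
                [1, 0, 0],
                [0, math.cos(math.radians(30)), -math.sin(math.radians(30))],
                [0, math.sin(math.radians(30)), math.cos(math.radians(30))],
            ]
        )
        rotated = st.copy()
        rotated.set_coords(st.coords @ rot.T)
        axis, _ = cd_axis(annotate_cd(rotated)[0])
        np.testing.assert_allclose(axis, rot @ [0, 0, 1], atol=1e-9)


class TestRigidInvariance:
    def test_descriptors_invariant_under_rigid_motion(self, ideal_cd):
        st, _ = ideal_cd
        tilts = (5.0, -3.0, 12.0, 0.0, 8.0, -7.0, 2.0)
        base, _ = build_ideal_cd(CDBuildSpec(tilts=tilts, rim_states=("gg", "gt", "gg", "tg", "gg", "gt", "gg")))
        ref_host = annotate_cd(base)[0]
        ref_pm = o4_polygon_metrics(ref_host)
        ref_tau = tilt_angles(ref_host).tau
        ref_states = [r.state for r in rim_states(ref_host)]
        rng = np.random.default_rng(1234)
        for _ in range(50):
            rot, trans = random_rigid_transform(rng)
            moved = transform_structure(base, rot, trans)
            host = annotate_cd(moved)[0]
            pm = o4_polygon_metrics(host)
            np.testing.assert_allclose(pm.d_K, ref_pm.d_K, atol=1e-9)
            np.testing.assert_allclose(pm.d, ref_pm.d, atol=1e-9)
            np.testing.assert_allclose(np.abs(pm.dev), np.abs(ref_pm.dev), atol=1e-9)
            np.testing.assert_allclose(tilt_angles(host).tau, ref_tau, atol=1e-6)
            assert [r.state for r in rim_states(host)] == ref_states
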