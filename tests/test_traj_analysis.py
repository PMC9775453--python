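"""Superposition, RMSD series, distance series and H-bond counting."""

import itertools
import math

import numpy as np
import pytest

from conftest import random_rigid_transform
from cycloscope.structure_io import Atom, Trajectory
from cycloscope.synthetic_data import (
    ComplexBuildSpec,
    GuestSpec,
    build_complex,
    build_trajectory,
)
from cycloscope.traj_analysis import (
    HBondCriteriaMD,
    contact_fraction,
    distance_series,
    hbond_count_series,
    kabsch_superpose,
    rmsd_series,
)


def quaternion_grid_superpose(ref, mob, n=24):
    """Oracle: brute-force search over a quaternion grid for the best rotation."""
    best = (np.inf, None)
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    vals = np.linspace(-1, 1, n)
    for q in itertools.product(vals, repeat=4):
        q = np.array(q)
        norm = np.linalg.norm(q)
        if norm < 1e-6:
            continue
        w, x, y, z = q / norm
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        rmsd = math.sqrt(float(((mob_c @ rot.T - ref_c) ** 2).sum(axis=1).mean()))
        if rmsd < best[0]:
            best = (rmsd, rot)
    return best


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered(self):
        pts = np.random.default_rng(1).normal(size=(4, 3))
        mob = pts + np.array([3.0, 4.0, 0.0])
        rot, trans, rmsd = kabsch_superpose(pts, mob)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(trans, [-3, -4, 0], atol=1e-9)

    def test_rotation_recovered_vs_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(4, 3)) * np.array([2, 1, 0.5])  # asymmetric
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        t = math.radians(37.0)
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        true_rot = np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)
        mob = ref @ true_rot.T
        rot, _, rmsd = kabsch_superpose(ref, mob)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(rot @ true_rot, np.eye(3), atol=1e-6)
        oracle_rmsd, _ = quaternion_grid_superpose(ref, mob, n=14)
        assert rmsd <= oracle_rmsd + 1e-9  # analytic answer beats the grid

    def test_proper_rotation_only(self):
        # mirrored coordinates must still yield det(R) = +1
        pts = np.random.default_rng(3).normal(size=(6, 3))
        mob = pts * np.array([-1, 1, 1])
        rot, _, _ = kabsch_superpose(pts, mob)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_fitted_never_worse_than_unfitted(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ref = rng.normal(size=(8, 3))
            mob = ref + rng.normal(scale=0.5, size=(8, 3))
            _, _, fitted = kabsch_superpose(ref, mob)
            unfitted = math.sqrt(float(((mob - ref) ** 2).sum(axis=1).mean()))
            assert fitted <= unfitted + 1e-12

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(4.0), [1.0, 0, 0])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)


def _toy_traj(frames):
    atoms = [Atom(f"C{i+1}", "C", frames[0][i]) for i in range(frames.shape[1])]
    return Trajectory(np.asarray(frames, dtype=float), atoms)


class TestRMSDSeries:
    def test_static_trajectory_all_zero(self):
        base = np.random.default_rng(0).normal(size=(6, 3))
        traj = _toy_traj(np.repeat(base[None], 5, axis=0))
        np.testing.assert_allclose(rmsd_series(traj).values, 0.0, atol=1e-12)

    def test_growing_translation_removed_by_fit(self):
        base = np.random.default_rng(1).normal(size=(6, 3))
        frames = np.array([base + k * np.array([0.5, 0, 0]) for k in range(8)])
        np.testing.assert_allclose(rmsd_series(_toy_traj(frames)).values, 0.0, atol=1e-9)

    def test_per_frame_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 3))
        wobble = base + rng.normal(scale=0.1, size=(8, 10, 3))
        plain = rmsd_series(_toy_traj(wobble)).values
        moved = np.empty_like(wobble)
        for k in range(8):
            rot, trans = random_rigid_transform(rng)
            moved[k] = wobble[k] @ rot.T + trans
        np.testing.assert_allclose(rmsd_series(_toy_traj(moved)).values, plain, atol=1e-9)

    def test_guest_drift_slope_recovered(self):
        st, _ = build_complex(ComplexBuildSpec(guest=GuestSpec()))
        guest = [i for i, a in enumerate(st.atoms) if a.residue_id == 101]
        host = [i for i, a in enumerate(st.atoms) if a.residue_id != 101]
        traj = build_trajectory(
            st, jitter_sd=0.0, drift=np.array([0, 0, 0.1]), drift_selection=guest, n_frames=12
        )
        series = rmsd_series(traj, measure_selection=guest, fit_selection=host)
        np.testing.assert_allclose(series.values, 0.1 * np.arange(12), atol=1e-6)

    def test_empty_selection_rejected(self):
        traj = _toy_traj(np.zeros((2, 4, 3)) + np.arange(4)[None, :, None])
        with pytest.raises(ValueError):
            rmsd_series(traj, measure_selection=[])


class TestDistanceSeries:
    def test_constant_pair(self):
        frames = np.zeros((5, 2, 3))
        frames[:, 1, 0] = 3.0
        series = distance_series(_toy_traj(frames), [(0, 1)])[0]
        np.testing.assert_allclose(series.values, 3.0)

    def test_jittered_mean_within_sampling_error(self):
        rng = np.random.default_rng(5)
        frames = np.zeros((1000, 2, 3))
        frames[:, 1, 0] = 4.0 + 0.2 * rng.standard_normal(1000)
        series = distance_series(_toy_traj(frames), [(0, 1)])[0]
        assert abs(series.values.mean() - 4.0) < 0.05

    def test_contact_fraction_zero_below_minimum(self):
        frames = np.zeros((10, 2, 3))
        frames[:, 1, 0] = 3.0
        series = distance_series(_toy_traj(frames), [(0, 1)])[0]
        assert contact_fraction(series, 2.5) == 0.0
        assert contact_fraction(series, 3.5) == 1.0

    def test_out_of_range_pair_rejected(self):
        with pytest.raises(ValueError):
            distance_series(_toy_traj(np.zeros((2, 2, 3))), [(0, 5)])


def _hbond_frames(n_frames, k_bonds, degrade_after=None):
    """k ideal O-H...O geometries per frame; optionally stretched mid-run."""
    n_atoms = 3 * k_bonds
    frames = np.zeros((n_frames, n_atoms, 3))
    atoms = []
    for b in range(k_bonds):
        o_d, h, o_a = 3 * b, 3 * b + 1, 3 * b + 2
        y = 10.0 * b
        for k in range(n_frames):
            stretch = 3.0 if degrade_after is not None and k >= degrade_after else 0.0
            frames[k, o_d] = [0, y, 0]
            frames[k, h] = [0.96, y, 0]
            frames[k, o_a] = [2.8 + stretch, y, 0]
        atoms += [("O", o_d), ("H", h), ("O", o_a)]
    meta = [Atom(f"{el}{i}", el, frames[0][i]) for el, i in atoms]
    traj = Trajectory(frames, meta)
    donors = [(3 * b, 3 * b + 1) for b in range(k_bonds)]
    acceptors = [3 * b + 2 for b in range(k_bonds)]
    return traj, donors, acceptors


class TestHBondCounts:
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_constructed_count(self, k):
        traj, donors, acceptors = _hbond_frames(6, k)
        series = hbond_count_series(traj, donors, acceptors)
        np.testing.assert_array_equal(series.counts, k)

    def test_degradation_drops_counts_at_constructed_frame(self):
        traj, donors, acceptors = _hbond_frames(10, 2, degrade_after=6)
        series = hbond_count_series(traj, donors, acceptors)
        np.testing.assert_array_equal(series.counts[:6], 2)
        np.testing.assert_array_equal(series.counts[6:], 0)

    def test_window_mean_of_constant_series(self):
        traj, donors, acceptors = _hbond_frames(8, 2)
        series = hbond_count_series(traj, donors, acceptors, window=3)
        np.testing.assert_allclose(series.window_mean, 2.0)
        assert series.window_mean.min() >= series.counts.min()
        assert series.window_mean.max() <= series.counts.max()

    def test_loosened_criteria_never_decrease_counts(self):
        traj, donors, acceptors = _hbond_frames(6, 3, degrade_after=3)
        tight = hbond_count_series(traj, donors, acceptors, HBondCriteriaMD(3.2, 150.0))
        loose = hbond_count_series(traj, donors, acceptors, HBondCriteriaMD(6.5, 90.0))
        assert np.all(loose.counts >= tight.counts)
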