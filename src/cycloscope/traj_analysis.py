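"""Time-series geometric analysis of coordinate trajectories.

RMSD follows the fit-then-measure convention: each frame is superposed on
the reference frame over a *fit* selection (Kabsch, proper rotation only)
and the RMSD is then evaluated over a possibly different *measure*
selection — e.g. fit on the host, measure the guest, to monitor guest drift
inside a cavity. Mass weighting is off by default.

Hydrogen-bond counting here uses MD-style criteria (d(D···A) ≤ 3.5 Å,
D–H···A ≥ 135°), deliberately distinct from the crystal-mode defaults in
:mod:`cycloscope.packing_interactions`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Trajectory

__all__ = [
    "RMSDSeries",
    "DistanceSeries",
    "HBondCountSeries",
    "HBondCriteriaMD",
    "kabsch_superpose",
    "rmsd_series",
    "distance_series",
    "contact_fraction",
    "hbond_count_series",
]


@dataclass
class RMSDSeries:
    values: np.ndarray
    fit_selection: np.ndarray
    measure_selection: np.ndarray
    reference: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values))


@dataclass
class DistanceSeries:
    pair: tuple[int, int]
    values: np.ndarray


@dataclass
class HBondCountSeries:
    counts: np.ndarray
    window_mean: np.ndarray
    window: int


@dataclass
class HBondCriteriaMD:
    da_max: float = 3.5
    dha_min: float = 135.0


_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


def _as_selection(sel, n_atoms: int) -> np.ndarray:
    if sel is None:
        return np.arange(n_atoms)
    idx = np.asarray(sel, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    if idx.min() < 0 or idx.max() >= n_atoms:
        raise ValueError(f"selection index out of range (n_atoms={n_atoms})")
    return idx


def kabsch_superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of *mobile* onto *reference*.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the (weighted) RMSD to
    *reference*. The rotation is always proper (det = +1).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must both have shape (n, 3)")
    if ref.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    w = np.ones(ref.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    ref_c = ref - (w[:, None] * ref).sum(axis=0)
    mob_c = mob - (w[:, None] * mob).sum(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection; rotation is ill-determined")
    h = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = (w[:, None] * ref).sum(axis=0) - rot @ (w[:, None] * mob).sum(axis=0)
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt((w * ((moved - ref) ** 2).sum(axis=1)).sum()))
    return rot, trans, rmsd


def rmsd_series(
    traj: Trajectory,
    measure_selection=None,
    fit_selection=None,
    reference: int = 0,
    mass_weighted: bool = False,
) -> RMSDSeries:
    """RMSD of each frame to a reference frame (default: the first).

    Each frame is superposed on the reference via ``fit_selection`` (default:
    all atoms), then RMSD is computed over ``measure_selection`` (default:
    all atoms).
    """
    fit = _as_selection(fit_selection, traj.n_atoms)
    meas = _as_selection(measure_selection, traj.n_atoms)
    weights = None
    if mass_weighted:
        weights = np.array(
            [_MASSES.get(traj.atoms[i].element.upper()[:1], 12.0) for i in fit]
        )
    ref = traj.frames[reference]
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(ref[fit], traj.frames[k][fit], weights)
        moved = traj.frames[k][meas] @ rot.T + trans
        values[k] = math.sqrt(float(((moved - ref[meas]) ** 2).sum(axis=1).mean()))
    return RMSDSeries(values, fit, meas, reference)


def distance_series(traj: Trajectory, pairs) -> list[DistanceSeries]:
    """Per-frame Euclidean distances for each (i, j) atom-index pair."""
    out = []
    for i, j in pairs:
        if not (0 <= i < traj.n_atoms and 0 <= j < traj.n_atoms):
            raise ValueError(f"atom index pair ({i}, {j}) out of range")
        d = np.linalg.norm(traj.frames[:, i, :] - traj.frames[:, j, :], axis=1)
        out.append(DistanceSeries((int(i), int(j)), d))
    return out


def contact_fraction(series: DistanceSeries, cutoff: float) -> float:
    """Share of frames in which the pair distance is at or below *cutoff*."""
    return float(np.mean(series.values <= cutoff))


def hbond_count_series(
    traj: Trajectory,
    donors,
    acceptors,
    criteria: HBondCriteriaMD | None = None,
    window: int = 100,
) -> HBondCountSeries:
    """Per-frame hydrogen-bond counts plus a running mean.

    ``donors`` is a list of ``(donor_index, hydrogen_index)`` pairs (donor H
    must be present in the topology for MD-style counting); ``acceptors`` a
    list of acceptor atom indices. A bond is counted when d(D···A) ≤ 3.5 Å
    and the D–H···A angle ≥ 135° (defaults, overridable).
    """
    crit = criteria or HBondCriteriaMD()
    donors = [(int(d), int(h)) for d, h in donors]
    acceptors = [int(a) for a in acceptors]
    for d, h in donors:
        _as_selection([d, h], traj.n_atoms)
    if acceptors:
        _as_selection(acceptors, traj.n_atoms)
    counts = np.zeros(traj.n_frames, dtype=int)
    for k in range(traj.n_frames):
        xyz = traj.frames[k]
        c = 0
        for d, h in donors:
            for a in acceptors:
                if a == d or a == h:
                    continue
                d_da = float(np.linalg.norm(xyz[d] - xyz[a]))
                if d_da > crit.da_max:
                    continue
                v1 = xyz[d] - xyz[h]
                v2 = xyz[a] - xyz[h]
                cosang = float(
                    np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
                )
                if math.degrees(math.acos(cosang)) >= crit.dha_min:
                    c += 1
        counts[k] = c
    window = max(1, int(window))
    kernel = np.ones(window)
    sums = np.convolve(counts, kernel, mode="full")[: traj.n_frames]
    norm = np.minimum(np.arange(1, traj.n_frames + 1), window)
    window_mean = sums / norm
    return HBondCountSeries(counts, window_mean, window)
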