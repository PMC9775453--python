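"""Synthetic inputs with known ground truth.

Every analysis in the package can be exercised on data whose correct answer
is known by construction:

* parametric idealized β-cyclodextrin macrocycles (seven 4C1-chair glucose
  templates on an ellipse, with controllable O4 radius, ellipticity,
  per-residue tilt, primary-rim rotamer states, substitution pattern and
  out-of-plane noise);
* two-host + threaded-guest complexes in prescribed mutual orientations;
* trajectories with seeded Gaussian jitter and deterministic drift;
* Higuchi–Connors phase-solubility curves (A_L and B-type) with replicate
  noise;
* per-frame MM/GBSA component tables with exactly prescribed sample moments.

The glucose template uses idealized internal coordinates (C–C 1.52 Å,
C–O 1.43 Å, tetrahedral-like angles): the goal is descriptor closure, not
chemical accuracy. All randomness flows through explicit seeds; identical
specs and seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structure_io import Atom, CrystalStructure, Trajectory
from .solubility import SolubilityDataset

__all__ = [
    "CDBuildSpec",
    "ComplexBuildSpec",
    "GuestSpec",
    "SolubilityGenSpec",
    "EnergyGenSpec",
    "build_ideal_cd",
    "build_complex",
    "build_trajectory",
    "gen_solubility",
    "gen_energy_frames",
]

BOND_CC = 1.52
BOND_CO = 1.43
RING_RADIUS = 1.3585   # in-plane radius of the chair hexagon
RING_PUCKER = 0.25     # alternating z displacement of the chair, Å
O4_C1_SPAN = 2.943     # O4(n) → C1(n) span along the chord toward O4(n-1), Å

_IDEAL_OMEGA = {"gg": -60.0, "gt": 60.0, "tg": 180.0}


@dataclass
class CDBuildSpec:
    """Parameters of an idealized 7-unit cyclodextrin macrocycle."""

    o4_radius: float = 5.05          # Å; circumradius of the O4 heptagon
    tilts: tuple[float, ...] = (0.0,) * 7   # degrees per residue
    ellipticity: float = 1.0          # max(d_K)/min(d_K), ≥ 1
    rim_states: tuple[str, ...] = ("gg",) * 7
    substitution: str = "native"      # native | 2,6-di-O-methyl | permethyl | hydroxypropyl(k)
    plane_noise: float = 0.0          # Å; SD of rigid per-residue out-of-plane shifts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.o4_radius <= 0:
            raise ValueError("o4_radius must be positive")
        if self.ellipticity < 1.0:
            raise ValueError("ellipticity must be ≥ 1")
        if len(self.tilts) != 7 or len(self.rim_states) != 7:
            raise ValueError("tilts and rim_states need exactly 7 entries")
        for s in self.rim_states:
            if s not in _IDEAL_OMEGA:
                raise ValueError(f"unknown rim state {s!r}")


@dataclass
class GuestSpec:
    """Generic three-fragment guest: aromatic ring — linker — saturated ring."""

    ring_a_angle: float = 70.0   # degrees vs host O4 plane (aromatic ring)
    ring_a_depth: float = 0.5    # Å along host axis from the O4 plane
    ring_b_angle: float = 70.0   # second (piperidine-like) ring
    ring_spacing: float = 5.0    # Å between ring centroids along the axis


@dataclass
class ComplexBuildSpec:
    hosts: tuple[CDBuildSpec, ...] = (CDBuildSpec(), CDBuildSpec())
    orientation: str = "head-to-tail"   # orientation of each pair
    axial_shift: float = 8.0            # Å between successive host centroids
    lateral_offset: float = 0.0         # Å perpendicular offset of upper hosts
    interplanar_angle: float = 0.0      # degrees, applied to the second host
    guest: GuestSpec | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.hosts) <= 4:
            raise ValueError("1–4 hosts supported")
        if self.orientation not in ("head-to-head", "tail-to-tail", "head-to-tail"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class SolubilityGenSpec:
    profile: str = "A_L"        # A_L | B_s | B_i
    S0: float = 0.0378          # mM, guest solubility in plain water
    slope: float = 0.15         # isotherm slope, (0, 1)
    cd_max: float = 60.0        # mM, top of the concentration range (A_L)
    plateau_start: float = 3.0  # mM; last linear level for B types
    decline_rate: float = 0.02  # mM dissolved per mM CD past the plateau
    noise_rel: float = 0.02     # relative Gaussian noise per replicate
    n_levels: int = 10
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.slope < 1.0:
            raise ValueError("slope must lie in (0, 1)")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be ≥ 0")
        if self.profile not in ("A_L", "B_s", "B_i"):
            raise ValueError(f"unsupported profile {self.profile!r}")


@dataclass
class EnergyGenSpec:
    """Per-frame MM/GBSA component generator with exact sample moments."""

    means: dict = field(
        default_factory=lambda: {"dE_vdW": -50.0, "dE_ele": -10.0, "dG_GB": 25.0, "dG_nonpolar": -5.0}
    )
    sds: dict = field(
        default_factory=lambda: {"dE_vdW": 4.0, "dE_ele": 4.0, "dG_GB": 4.0, "dG_nonpolar": 0.3}
    )
    correlation: float | np.ndarray = 0.0
    n_frames: int = 1000
    tds: float | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about *axis* (right-handed, degrees)."""
    axis = _unit(np.asarray(axis, dtype=float))
    t = math.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


def _place_by_torsion(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom D given chain A-B-C, |CD|, angle BCD and torsion ABCD."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = _unit(c - b)
    n = _unit(np.cross(bc, b - a))
    m = np.cross(n, bc)
    theta = math.radians(angle_deg)
    phi = math.radians(180.0 + torsion_deg)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[2]


def _glucose_template(rim_state: str, substitution: str) -> dict[str, np.ndarray]:
    """Idealized 4C1 glucose in the residue frame.

    Frame convention: O4 at the origin; +x toward the previous residue's O4
    (C1 lies exactly on that line so the tilt-defining quadrilateral
    O4(n−1)–C1–C4–O4(n) is exactly planar at zero tilt); +y radially
    outward; +z toward the primary (O6) rim.
    """
    o4 = np.zeros(3)
    c1t = np.array([O4_C1_SPAN, 0.0, 0.0])
    d14 = 2.0 * math.hypot(RING_RADIUS, RING_PUCKER)
    x4 = (BOND_CO**2 + O4_C1_SPAN**2 - d14**2) / (2.0 * O4_C1_SPAN)
    c4t = np.array([x4, math.sqrt(BOND_CO**2 - x4**2), 0.0])

    # canonical chair: O5, C1, C2, C3, C4, C5 on a puckered hexagon
    j = np.arange(6)
    ring0 = np.column_stack(
        [
            RING_RADIUS * np.cos(j * math.pi / 3),
            RING_RADIUS * np.sin(j * math.pi / 3),
            RING_PUCKER * (-1.0) ** (j + 1),
        ]
    )
    # rigid-map the ring so C1 -> c1t, C4 -> c4t; the leftover spin about the
    # C1-C4 axis is fixed by making the ring stand upright (ring normal
    # horizontal, as glucose residues do in a cyclodextrin torus), with the
    # C5/O5 edge on the +z (primary) side.
    v = ring0[4] - ring0[1]
    u = c4t - c1t
    axis = np.cross(v, u)
    if np.linalg.norm(axis) < 1e-12:
        r1 = np.eye(3)
    else:
        ang = math.degrees(math.acos(np.clip(_unit(v) @ _unit(u), -1, 1)))
        r1 = _rotation(axis, ang)
    pts = (ring0 - ring0[1]) @ r1.T
    u_hat = _unit(u)
    n0 = _plane_normal(pts)
    # solve (R(u, psi) n0) . z = 0; u is horizontal so the equation reduces
    # to A cos psi + B sin psi = 0
    a_c = float(n0[2])
    b_c = float(np.cross(u_hat, n0)[2])
    psi0 = math.degrees(math.atan2(-a_c, b_c))
    best = None
    for psi in (psi0, psi0 + 180.0):
        cand = pts @ _rotation(u_hat, psi).T + c1t
        if best is None or cand[5][2] > best[0]:
            best = (cand[5][2], cand)  # C5 (primary side) up
    pts = best[1]
    z_up = np.array([0.0, 0.0, 1.0])

    atoms = {"O5": pts[0], "C1": pts[1], "C2": pts[2], "C3": pts[3], "C4": pts[4], "C5": pts[5], "O4": o4}
    centroid = pts.mean(axis=0)

    def _horiz_out(p):
        h = p - centroid
        h[2] = 0.0
        return _unit(h) if np.linalg.norm(h) > 1e-9 else np.array([0.0, 1.0, 0.0])

    # C6 tetrahedral at C5 w.r.t. its ring neighbours O5 and C4, upper branch:
    # this makes the omega/omega' torsion split close to the ideal 120 deg
    u1 = _unit(pts[0] - pts[5])   # C5 -> O5
    u2 = _unit(pts[4] - pts[5])   # C5 -> C4
    bis = _unit(u1 + u2)
    perp = _unit(np.cross(u1, u2))
    a_t = math.cos(math.radians(109.47)) / float(bis @ u1)
    b_t = math.sqrt(max(0.0, 1.0 - a_t * a_t))
    # the -perp branch is the D-sugar chirality (omega' = omega + 120 deg
    # under the IUPAC torsion sign); with the C5-up spin branch it also
    # points toward the primary rim
    d6 = a_t * bis - b_t * perp
    atoms["C6"] = pts[5] + BOND_CC * _unit(d6)
    atoms["O6"] = _place_by_torsion(
        atoms["O5"], atoms["C5"], atoms["C6"], BOND_CO, 109.47, _IDEAL_OMEGA[rim_state]
    )
    for cn, on in (("C2", "O2"), ("C3", "O3")):
        c = atoms[cn]
        atoms[on] = c + BOND_CO * _unit(-z_up + 0.45 * _horiz_out(c))
    if substitution == "2,6-di-O-methyl":
        subs = ("O2", "O6")
    elif substitution == "permethyl":
        subs = ("O2", "O3", "O6")
    elif substitution.startswith("hydroxypropyl"):
        subs = ("hp",)
    else:
        subs = ()
    for o in subs:
        if o == "hp":
            # 2-hydroxypropyl chain on O2: O2-CH1-CH2(-OH3)-CH3
            d = _unit(atoms["O2"] - atoms["C2"])
            side = _unit(np.cross(d, z_up))
            atoms["CH1"] = atoms["O2"] + BOND_CO * d
            atoms["CH2"] = atoms["CH1"] + BOND_CC * _unit(d + 0.5 * side)
            atoms["CH3"] = atoms["CH2"] + BOND_CC * _unit(d - 0.5 * side)
            atoms["OH2"] = atoms["CH2"] + BOND_CO * _unit(side + 0.3 * z_up)
        else:
            parent_c = atoms["C6"] if o == "O6" else atoms[f"C{o[1]}"]
            atoms[f"CM{o[1]}"] = atoms[o] + BOND_CO * _unit(atoms[o] - parent_c)
    return atoms


def _o4_positions(spec: CDBuildSpec) -> np.ndarray:
    """Seven O4 sites on an ellipse with exact max/min centroid-distance ratio.

    The ellipse semi-axes are chosen so that over the seven discrete
    parametric angles 2πn/7 the largest d_K equals a and the smallest equals
    a/ellipticity exactly (the n = 2, 5 sites realize the minimum).
    """
    phis = 2.0 * math.pi * np.arange(7) / 7.0
    e = spec.ellipticity
    if e == 1.0:
        a = b = spec.o4_radius
    else:
        a = spec.o4_radius * math.sqrt(e)
        c2 = math.cos(phis[2]) ** 2
        b = math.sqrt((a / e) ** 2 - a**2 * c2) / math.sqrt(1.0 - c2)
    return np.column_stack([a * np.cos(phis), b * np.sin(phis), np.zeros(7)])


def build_ideal_cd(
    spec: CDBuildSpec, residue_base: int = 0
) -> tuple[CrystalStructure, dict]:
    """Construct an idealized macrocycle; returns (structure, ground truth).

    Residue *n*'s O4 is glycosidically adjacent to residue *n+1*'s C1; atoms
    are labelled by role (C1..C6, O2..O6, CM*/CH*) with residue ids
    ``residue_base + 1 .. residue_base + 7``.
    """
    rng = np.random.default_rng(spec.seed)
    p = _o4_positions(spec)
    atoms: list[Atom] = []
    z_hat = np.array([0.0, 0.0, 1.0])
    z_offsets = (
        rng.normal(0.0, spec.plane_noise, 7) if spec.plane_noise > 0 else np.zeros(7)
    )
    for n in range(7):
        template = _glucose_template(spec.rim_states[n], spec.substitution)
        chord = _unit(p[(n - 1) % 7] - p[n])
        y_hat = _unit(np.cross(z_hat, chord))
        frame = np.column_stack([chord, y_hat, z_hat])
        rot_tilt = _rotation(chord, spec.tilts[n])
        for role, local in template.items():
            world = p[n] + rot_tilt @ (frame @ local)
            world = world + z_offsets[n] * z_hat
            atoms.append(
                Atom(
                    role,
                    role[0] if role[0] in "CON" else "C",
                    world,
                    residue_id=residue_base + n + 1,
                )
            )
    structure = CrystalStructure(atoms, fractional=False)
    truth = {
        "o4_positions": p + z_offsets[:, None] * z_hat,
        "d_K": np.linalg.norm(p - p.mean(axis=0), axis=1),
        "tilts": np.asarray(spec.tilts, dtype=float),
        "rim_states": tuple(spec.rim_states),
        "ellipticity": spec.ellipticity,
        "substitution": spec.substitution,
        "axis": z_hat.copy(),
        "center": p.mean(axis=0),
        "z_offsets": z_offsets,
    }
    return structure, truth


# ---------------------------------------------------------------------------
# Complexes
# ---------------------------------------------------------------------------

def _ring_atoms(center, normal, radius, n, symbols, start_label):
    """Planar regular ring of *n* atoms around *center* with plane normal."""
    normal = _unit(np.asarray(normal, dtype=float))
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(float(seed_vec @ normal)) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    e1 = _unit(seed_vec - (seed_vec @ normal) * normal)
    e2 = np.cross(normal, e1)
    out = []
    for k in range(n):
        ang = 2 * math.pi * k / n
        pos = center + radius * (math.cos(ang) * e1 + math.sin(ang) * e2)
        out.append(Atom(f"{start_label}{k + 1}", symbols[k % len(symbols)], pos, residue_id=101))
    return out


def _build_guest(spec: GuestSpec, o4_plane_z: float = 0.0) -> tuple[list[Atom], dict]:
    """Three-fragment guest threaded along +z above the host O4 plane."""
    atoms: list[Atom] = []
    ca = np.array([0.0, 0.0, o4_plane_z + spec.ring_a_depth])
    na = _rotation([0.0, 1.0, 0.0], spec.ring_a_angle) @ np.array([0.0, 0.0, 1.0])
    ring_a = _ring_atoms(ca, na, 1.39, 6, ["C"], "GA")
    atoms += ring_a
    # dioxole-like oxygens flanking the aromatic ring
    e_out = _unit(np.cross(na, [0.0, 0.0, 1.0])) if abs(na[2]) < 0.999 else np.array([1.0, 0.0, 0.0])
    atoms.append(Atom("GOA1", "O", ca + 2.3 * e_out + 0.55 * na, residue_id=101))
    atoms.append(Atom("GOA2", "O", ca + 2.3 * e_out - 0.55 * na, residue_id=101))
    cb = ca + np.array([0.0, 0.0, spec.ring_spacing])
    for k in range(4):
        frac = (k + 1) / 5.0
        pos = ca * (1 - frac) + cb * frac + np.array([0.25 * ((-1) ** k), 0.0, 0.0])
        atoms.append(Atom(f"GL{k + 1}", "C", pos, residue_id=101))
    atoms.append(Atom("GLO", "O", ca + np.array([0.9, 0.0, 0.5 * spec.ring_spacing]), residue_id=101))
    nb = _rotation([0.0, 1.0, 0.0], spec.ring_b_angle) @ np.array([0.0, 0.0, 1.0])
    ring_b = _ring_atoms(cb, nb, 1.45, 6, ["C", "C", "C", "N", "C", "C"], "GB")
    atoms += ring_b
    truth = {
        "ring_a_indices": list(range(6)),
        "ring_a_angle": spec.ring_a_angle,
        "ring_a_depth": spec.ring_a_depth,
        "ring_b_angle": spec.ring_b_angle,
    }
    return atoms, truth


def build_complex(spec: ComplexBuildSpec) -> tuple[CrystalStructure, dict]:
    """Assemble hosts (stacked along +z) and an optional threaded guest.

    Host 0 sits at the origin with its primary rim up (+z). Upper hosts are
    displaced by ``axial_shift`` along z (plus ``lateral_offset`` along x),
    flipped according to ``orientation`` and, for the second host, rotated
    by ``interplanar_angle`` about x. The construction labels are returned
    as ground truth for closure tests.
    """
    all_atoms: list[Atom] = []
    flips: list[bool] = []
    for k in range(len(spec.hosts)):
        if spec.orientation == "head-to-tail":
            flips.append(False)
        elif spec.orientation == "tail-to-tail":
            flips.append(k % 2 == 1)
        else:  # head-to-head
            flips.append(k % 2 == 0)
    for k, hspec in enumerate(spec.hosts):
        host_struct, _ = build_ideal_cd(hspec, residue_base=10 * k)
        coords = host_struct.coords
        center = coords.mean(axis=0)
        coords = coords - center
        if flips[k]:
            coords = coords @ _rotation([1.0, 0.0, 0.0], 180.0).T
        if k == 1 and spec.interplanar_angle:
            coords = coords @ _rotation([1.0, 0.0, 0.0], spec.interplanar_angle).T
        offset = np.array(
            [spec.lateral_offset if k > 0 else 0.0, 0.0, k * spec.axial_shift]
        )
        coords = coords + offset
        for atom, pos in zip(host_struct.atoms, coords):
            all_atoms.append(replace(atom, coords=pos))
    truth: dict = {
        "orientation": spec.orientation,
        "axial_shift": spec.axial_shift,
        "lateral_offset": spec.lateral_offset,
        "interplanar_angle": spec.interplanar_angle,
        "n_hosts": len(spec.hosts),
        "flips": flips,
    }
    if spec.guest is not None:
        guest_atoms, guest_truth = _build_guest(spec.guest)
        offset = len(all_atoms)
        guest_truth["ring_a_indices"] = [offset + i for i in guest_truth["ring_a_indices"]]
        all_atoms += guest_atoms
        truth.update(guest_truth)
    structure = CrystalStructure(all_atoms, fractional=False)
    coords = structure.coords
    groups = np.array([a.residue_id // 10 if a.residue_id < 100 else 99 for a in all_atoms])
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(1.5):
        if groups[i] != groups[j]:
            import warnings

            warnings.warn("assembled units have overlapping heavy atoms (< 1.5 A)")
            break
    return structure, truth


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def build_trajectory(
    base: CrystalStructure,
    jitter_sd: float = 0.0,
    drift: np.ndarray | None = None,
    drift_selection=None,
    n_frames: int = 10,
    seed: int = 0,
    timestep: float = 1.0,
) -> Trajectory:
    """Frames = base + seeded Gaussian jitter + deterministic per-frame drift.

    ``drift`` is a 3-vector applied cumulatively (k·drift at frame k) to the
    atoms in ``drift_selection`` (default: all atoms).
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be ≥ 0")
    st = base.to_cartesian()
    coords = st.coords
    rng = np.random.default_rng(seed)
    sel = (
        np.arange(coords.shape[0])
        if drift_selection is None
        else np.asarray(drift_selection, dtype=int)
    )
    frames = np.empty((n_frames, coords.shape[0], 3))
    for k in range(n_frames):
        frame = coords.copy()
        if jitter_sd > 0:
            frame = frame + rng.normal(0.0, jitter_sd, frame.shape)
        if drift is not None:
            frame[sel] += k * np.asarray(drift, dtype=float)
        frames[k] = frame
    return Trajectory(frames, [replace(a, coords=a.coords.copy()) for a in st.atoms], timestep)


# ---------------------------------------------------------------------------
# Phase-solubility data
# ---------------------------------------------------------------------------

def gen_solubility(spec: SolubilityGenSpec) -> tuple[SolubilityDataset, dict]:
    """Generate a phase-solubility dataset with known ground truth.

    A_L: S(C) = S0 + slope·C over ``n_levels`` between 1 mM and ``cd_max``.
    B types: linear over three levels up to ``plateau_start``, then (B_s) a
    two-level plateau, then a decline of ``decline_rate`` per mM; B_i omits
    the plateau. Replicate noise is relative Gaussian, seeded.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.profile == "A_L":
        cd = np.linspace(1.0, spec.cd_max, spec.n_levels)
        s_true = spec.S0 + spec.slope * cd
        lin_stop = spec.n_levels
    else:
        lin = np.linspace(1.0, spec.plateau_start, 3)
        step = max(spec.plateau_start / 2.0, 1.0)
        if spec.profile == "B_s":
            plat = spec.plateau_start + step * np.array([1.0, 2.0])
        else:
            plat = np.empty(0)
        n_decl = max(spec.n_levels - 3 - len(plat), 2)
        start = (plat[-1] if len(plat) else spec.plateau_start) + step
        decl = start + step * np.arange(n_decl)
        cd = np.concatenate([lin, plat, decl])
        smax = spec.S0 + spec.slope * spec.plateau_start
        s_true = np.where(
            cd <= spec.plateau_start,
            spec.S0 + spec.slope * cd,
            np.maximum(
                smax - spec.decline_rate * np.maximum(cd - (plat[-1] if len(plat) else spec.plateau_start), 0.0),
                0.0,
            ),
        )
        lin_stop = 3
    if spec.noise_rel > 0:
        reps = s_true[None, :] * (
            1.0 + rng.normal(0.0, spec.noise_rel, (spec.n_replicates, len(cd)))
        )
        means = reps.mean(axis=0)
        sds = reps.std(axis=0, ddof=1) if spec.n_replicates > 1 else np.zeros(len(cd))
    else:
        means = s_true.copy()
        sds = np.zeros(len(cd))
    dataset = SolubilityDataset(cd, np.maximum(means, 0.0), sds, spec.n_replicates)
    truth = {
        "profile": spec.profile,
        "slope": spec.slope,
        "S0": spec.S0,
        "linear_range": (0, lin_stop),
        "Kc": spec.slope / ((spec.S0 * 1e-3) * (1.0 - spec.slope)),
        "CE": 100.0 * spec.slope / (1.0 - spec.slope),
    }
    return dataset, truth


# ---------------------------------------------------------------------------
# Energy-frame tables
# ---------------------------------------------------------------------------

def gen_energy_frames(spec: EnergyGenSpec) -> tuple[pd.DataFrame, dict]:
    """Correlated Gaussian component draws with *exact* sample moments.

    Columns are drawn from a multivariate normal with the requested pairwise
    correlation, then constructively recentred and rescaled so that every
    column's sample mean and SD (ddof=1) equal the spec exactly — parameter
    recovery by :func:`cycloscope.energetics.combine_frames` is then exact
    rather than statistical.
    """
    cols = list(spec.means)
    k = len(cols)
    if np.isscalar(spec.correlation):
        corr = np.full((k, k), float(spec.correlation))
        np.fill_diagonal(corr, 1.0)
    else:
        corr = np.asarray(spec.correlation, dtype=float)
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    if spec.n_frames < 2:
        raise ValueError("need at least 2 frames to control sample moments")
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((spec.n_frames, k)) @ chol.T
    data = {}
    for i, c in enumerate(cols):
        col = z[:, i]
        sd = col.std(ddof=1)
        col = (col - col.mean()) / (sd if sd > 0 else 1.0)
        data[c] = col * spec.sds.get(c, 0.0) + spec.means[c]
    df = pd.DataFrame(data)
    if spec.tds is not None:
        df["TdS"] = spec.tds
    truth = {"means": dict(spec.means), "sds": dict(spec.sds), "tds": spec.tds}
    return df, truth
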