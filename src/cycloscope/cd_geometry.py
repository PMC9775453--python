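"""Per-macrocycle conformational descriptors of cyclodextrin hosts.

A β-cyclodextrin macrocycle is described here the way the carbohydrate
crystallography literature describes it:

* the best-fit (least-squares) plane through the seven glycosidic O4 atoms
  and the signed deviations *dev* of each O4 from it;
* the O4 heptagon metrics — distances *d_K* from each O4 to the heptagon
  centroid, adjacent O4···O4 distances *d*, and the ellipticity
  max(d_K)/min(d_K);
* the glucose tilt angles τ between the O4 mean plane and the plane through
  O4(n−1), C1(n), C4(n), O4(n), signed positive when the residue's primary
  (O6) side leans toward the approximate sevenfold cavity axis;
* the exocyclic C5–C6 rotamer state (gg/gt/tg) from the ω = O5–C5–C6–O6 and
  ω′ = C4–C5–C6–O6 torsions;
* Cremer–Pople puckering (Q, θ, φ) of each pyranose ring and a 4C1 chair
  check;
* the approximate sevenfold cavity axis (O4-plane normal oriented from the
  secondary toward the primary rim).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import CDHost

__all__ = [
    "PlaneFit",
    "PolygonMetrics",
    "TiltAngles",
    "RimState",
    "PuckerResult",
    "fit_mean_plane",
    "o4_polygon_metrics",
    "tilt_angle",
    "tilt_angles",
    "rim_torsion_state",
    "rim_states",
    "classify_rotamer",
    "ring_pucker",
    "host_puckers",
    "cd_axis",
    "torsion",
    "host_descriptor_table",
]


@dataclass
class PlaneFit:
    """Least-squares plane: unit normal, centroid, rms and signed deviations."""

    normal: np.ndarray
    point: np.ndarray
    rms_dev: float
    per_point_dev: np.ndarray

    def signed_distance(self, xyz: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(xyz) - self.point) @ self.normal


@dataclass
class PolygonMetrics:
    d_K: np.ndarray          # O4 to heptagon centroid, Å
    d: np.ndarray            # adjacent O4-O4, ring order, Å
    dev: np.ndarray          # signed deviation from O4 mean plane, Å
    ellipticity: float


@dataclass
class TiltAngles:
    tau: np.ndarray          # signed degrees, one per residue


@dataclass
class RimState:
    omega: float             # O5-C5-C6-O6, degrees
    omega_prime: float       # C4-C5-C6-O6, degrees
    state: str               # gg / gt / tg / both / unclassified
    reason: str = ""


@dataclass
class PuckerResult:
    Q: float                 # total puckering amplitude, Å
    theta: float             # polar puckering angle, degrees
    phi: float               # azimuthal puckering angle, degrees
    is_4C1: bool


def fit_mean_plane(points: np.ndarray, orient: np.ndarray | None = None) -> PlaneFit:
    """Best-fit plane minimizing the sum of squared orthogonal distances.

    ``orient`` (optional direction) resolves the sign of the normal; without
    it the normal is flipped so its largest-magnitude component is positive,
    which is deterministic for any non-degenerate point set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("points are collinear; plane is undefined")
    normal = vt[2]
    if orient is not None:
        if float(normal @ np.asarray(orient, dtype=float)) < 0:
            normal = -normal
    elif normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    dev = centered @ normal
    return PlaneFit(normal, centroid, float(np.sqrt(np.mean(dev**2))), dev)


def o4_polygon_metrics(host: CDHost) -> PolygonMetrics:
    """Heptagon metrics of the seven glycosidic O4 atoms.

    The heptagon centroid is the arithmetic mean of the O4 positions (for
    near-planar rings this differs from the plane-projected mean by <1e-3 Å).
    """
    o4 = host.o4_coords
    centroid = o4.mean(axis=0)
    d_k = np.linalg.norm(o4 - centroid, axis=1)
    d = np.linalg.norm(o4 - np.roll(o4, -1, axis=0), axis=1)
    plane = fit_mean_plane(o4, orient=cd_axis(host)[0])
    return PolygonMetrics(d_k, d, plane.per_point_dev, float(d_k.max() / d_k.min()))


def cd_axis(host: CDHost) -> tuple[np.ndarray, np.ndarray]:
    """Approximate sevenfold axis: O4-plane normal anchored at the O4 centroid.

    Oriented from the secondary (O2/O3) rim toward the primary (O6) rim.
    """
    o4 = host.o4_coords
    plane = fit_mean_plane(o4)
    normal, anchor = plane.normal, plane.point
    primary = _rim_centroid(host, ("O6", "C6", "C5"))
    secondary = _rim_centroid(host, ("O2", "O3", "C2", "C3"))
    direction = primary - secondary
    if float(normal @ direction) < 0:
        normal = -normal
    return normal, anchor


def _rim_centroid(host: CDHost, roles: tuple[str, ...]) -> np.ndarray:
    pts = []
    for n in range(7):
        for role in roles:
            if role in host.residues[n]:
                pts.append(host.structure.atoms[host.residues[n][role]].coords)
                break
    return np.mean(pts, axis=0)


def tilt_angle(host: CDHost, n: int) -> float:
    """Signed tilt τ of residue *n* (degrees).

    Unsigned value: angle between the O4 mean-plane normal and the normal of
    the plane through O4(n−1), C1(n), C4(n), O4(n), folded to [0°, 90°].
    Sign: positive when the residue's primary (O6) side leans toward the
    cavity axis, measured by the dot product of the residue-plane normal
    (oriented toward the residue's O6 side) with the inward radial direction
    at O4(n).
    """
    res = host.residues[n % 7]
    prev = host.residues[(n - 1) % 7]
    for role, where in (("O4", prev), ("C1", res), ("C4", res), ("O4", res)):
        if role not in where:
            raise ValueError(f"residue {n}: role {role!r} missing for tilt angle")
    atoms = host.structure.atoms
    quad = np.array(
        [
            atoms[prev["O4"]].coords,
            atoms[res["C1"]].coords,
            atoms[res["C4"]].coords,
            atoms[res["O4"]].coords,
        ]
    )
    axis, anchor = cd_axis(host)
    o4_plane = fit_mean_plane(host.o4_coords, orient=axis)
    res_plane = fit_mean_plane(quad)
    dot = float(res_plane.normal @ o4_plane.normal)
    cross = float(np.linalg.norm(np.cross(res_plane.normal, o4_plane.normal)))
    angle = math.degrees(math.atan2(cross, abs(dot)))  # well-conditioned near 0
    # orient the residue normal toward the primary (C5/C6/O6) side; the mean
    # of the primary-side carbons is a robust reference (O6 itself can lie
    # almost in the residue plane when the rim points outward)
    normal = res_plane.normal
    refs = [atoms[res[role]].coords for role in ("C5", "C6", "O6") if role in res]
    ref = np.mean(refs, axis=0) if refs else anchor + axis
    if float(normal @ (ref - res_plane.point)) < 0:
        normal = -normal
    o4n = atoms[res["O4"]].coords
    radial = anchor - o4n
    inward = radial - (radial @ axis) * axis
    sign = 1.0 if float(normal @ inward) >= 0 else -1.0
    return sign * angle


def tilt_angles(host: CDHost) -> TiltAngles:
    return TiltAngles(np.array([tilt_angle(host, n) for n in range(7)]))


def torsion(p0, p1, p2, p3) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention (−180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = -math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


_IDEAL_ROTAMERS = {"gg": (-60.0, 60.0), "gt": (60.0, 180.0), "tg": (180.0, -60.0)}
ROTAMER_WINDOW = 30.0  # degrees, per torsion


def _ang_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def classify_rotamer(omega: float, omega_prime: float, window: float = ROTAMER_WINDOW) -> str:
    """gg/gt/tg assignment from the (ω, ω′) torsion pair, else ``unclassified``."""
    for name, (w, wp) in _IDEAL_ROTAMERS.items():
        if _ang_diff(omega, w) <= window and _ang_diff(omega_prime, wp) <= window:
            return name
    return "unclassified"


def rim_torsion_state(host: CDHost, n: int, alt_site: str | None = None) -> RimState:
    """Rotamer state of the C5–C6 exocyclic bond of residue *n*.

    States are assigned by nearest ideal (ω, ω′) pair within a ±30° window
    on both torsions: gg (−60°, +60°), gt (+60°, 180°), tg (180°, −60°);
    anything outside the windows is ``unclassified``. Disordered O6 sites are
    handled by :func:`rim_states`, which reports ``both``.
    """
    res = host.residues[n % 7]
    for role in ("C4", "C5", "C6", "O5", "O6"):
        if role not in res:
            return RimState(math.nan, math.nan, "unclassified", reason=f"missing {role}")
    atoms = host.structure.atoms
    p = {r: atoms[res[r]].coords for r in ("C4", "C5", "C6", "O5", "O6")}
    omega = torsion(p["O5"], p["C5"], p["C6"], p["O6"])
    omega_p = torsion(p["C4"], p["C5"], p["C6"], p["O6"])
    return RimState(omega, omega_p, classify_rotamer(omega, omega_p))


def rim_states(host: CDHost) -> list[RimState]:
    return [rim_torsion_state(host, n) for n in range(7)]


def ring_pucker(ring_coords: np.ndarray) -> PuckerResult:
    """Cremer–Pople puckering parameters of a six-membered ring.

    ``ring_coords`` must be the six ring atoms in the order
    O5–C1–C2–C3–C4–C5. Under this ordering the 4C1 chair of a
    D-glucopyranose lies near the θ = 0 pole; ``is_4C1`` is true when
    θ ≤ 30° and the ring is actually puckered (Q > 0.1 Å).
    """
    xyz = np.asarray(ring_coords, dtype=float)
    if xyz.shape != (6, 3):
        raise ValueError(f"need exactly 6 ring atoms, got shape {xyz.shape}")
    n = 6
    centered = xyz - xyz.mean(axis=0)
    j = np.arange(n)
    r1 = (centered * np.sin(2 * np.pi * j / n)[:, None]).sum(axis=0)
    r2 = (centered * np.cos(2 * np.pi * j / n)[:, None]).sum(axis=0)
    normal = np.cross(r1, r2)
    normal /= np.linalg.norm(normal)
    z = centered @ normal
    q2_cos = math.sqrt(2.0 / n) * float((z * np.cos(4 * np.pi * j / n)).sum())
    q2_sin = -math.sqrt(2.0 / n) * float((z * np.sin(4 * np.pi * j / n)).sum())
    q2 = math.hypot(q2_cos, q2_sin)
    q3 = float((z * np.cos(np.pi * j)).sum()) / math.sqrt(n)
    big_q = math.sqrt(float((z**2).sum()))
    if big_q < 1e-12:
        return PuckerResult(0.0, 0.0, 0.0, False)
    theta = math.degrees(math.acos(max(-1.0, min(1.0, q3 / big_q))))
    phi = math.degrees(math.atan2(q2_sin, q2_cos)) % 360.0
    return PuckerResult(big_q, theta, phi, bool(big_q > 0.1 and theta <= 30.0))


def host_puckers(host: CDHost) -> list[PuckerResult]:
    ring_order = ("O5", "C1", "C2", "C3", "C4", "C5")
    return [ring_pucker(host.residue_coords(n, ring_order)) for n in range(7)]


def host_descriptor_table(host: CDHost):
    """One row per residue: d_K, d, dev, τ, ω, ω′, rotamer state, Q, θ, 4C1."""
    import pandas as pd

    poly = o4_polygon_metrics(host)
    taus = tilt_angles(host).tau
    rims = rim_states(host)
    pucks = host_puckers(host)
    return pd.DataFrame(
        {
            "residue": np.arange(1, 8),
            "d_K": poly.d_K,
            "d": poly.d,
            "dev": poly.dev,
            "tau": taus,
            "omega": [r.omega for r in rims],
            "omega_prime": [r.omega_prime for r in rims],
            "rotamer": [r.state for r in rims],
            "Q": [p.Q for p in pucks],
            "theta": [p.theta for p in pucks],
            "is_4C1": [p.is_4C1 for p in pucks],
        }
    )
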