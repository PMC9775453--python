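"""Host-pair and guest–host arrangement, crystal packing, and contacts.

Covers the descriptors used to characterise how two cyclodextrin hosts face
each other (head-to-head / tail-to-tail / head-to-tail, interplanar angle,
centroid shifts), how a guest ring sits in a host cavity (ring-plane angle
vs the O4 plane, penetration depth), whether stacked complex units pack in
the channel (CH) mode, and geometric hydrogen-bond / close-contact
detection.

Hydrogen-bond criteria default to conventional small-molecule
crystallographic values and work donor-H-free (deposited water hydrogens
are routinely absent from cyclodextrin structures): when no hydrogen is
modelled, only the donor–acceptor distance is tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cd_geometry import cd_axis, fit_mean_plane
from .structure_io import BOND_CUTOFF, CDHost, CrystalStructure, expand_symmetry

__all__ = [
    "HostPairGeometry",
    "GuestOrientation",
    "PackingMode",
    "Contact",
    "ContactCriteria",
    "host_pair_geometry",
    "guest_orientation",
    "packing_mode",
    "find_hbonds",
    "find_close_contacts",
]

#: dot-product threshold on oriented host axes deciding the orientation class
ORIENTATION_DOT = 0.5
#: successive-unit shift (Å) at or below which stacking counts as channel mode
CH_SHIFT_MAX = 3.2


@dataclass
class HostPairGeometry:
    interplanar_angle: float   # degrees, [0, 90]
    centroid_distance: float   # Å
    lateral_offset: float      # Å, ⟂ to the mean axis
    axial_shift: float         # Å, ∥ to the mean axis
    orientation: str           # head-to-head / tail-to-tail / head-to-tail


@dataclass
class GuestOrientation:
    ring_plane_angle: float    # degrees vs host O4 plane, [0, 90]
    penetration_depth: float   # signed Å along host axis (positive → primary rim)


@dataclass
class PackingMode:
    successive_shift: float    # Å between consecutive stacked units
    axis_cell_angle: float     # degrees between CD axis and the stacking axis
    mode: str                  # "CH" or "other"


@dataclass
class Contact:
    kind: str                  # O-H...O / C-H...O / H...H / other
    donor: str
    acceptor: str
    d_DA: float
    d_HA: float | None = None
    angle_DHA: float | None = None


@dataclass
class ContactCriteria:
    """Geometric cutoffs; crystal-structure defaults (inclusive boundaries)."""

    hbond_da_max: float = 3.4     # donor...acceptor, Å
    hbond_ha_max: float = 2.7     # H...acceptor, Å (when H modelled)
    hbond_dha_min: float = 120.0  # D-H...A angle, degrees
    ch_o_ha_max: float = 2.9      # C-H...O H...O distance, Å
    ch_o_dha_min: float = 110.0   # C-H...O angle, degrees
    hh_max: float = 2.4           # H...H, twice the H van der Waals radius, Å
    donors: tuple[str, ...] = ("O", "N")
    acceptors: tuple[str, ...] = ("O", "N")


def _fold_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    u1 = n1 / np.linalg.norm(n1)
    u2 = n2 / np.linalg.norm(n2)
    dot = float(u1 @ u2)
    cross = float(np.linalg.norm(np.cross(u1, u2)))
    return math.degrees(math.atan2(cross, abs(dot)))


def host_pair_geometry(host_a: CDHost, host_b: CDHost) -> HostPairGeometry:
    """Mutual arrangement of two annotated hosts.

    The orientation class follows the signed (secondary→primary) host axes:
    with d̂ the unit vector from A's O4 centroid to B's, tail-to-tail means
    A's axis points toward B and B's toward A (primary rims facing),
    head-to-head the reverse, and head-to-tail that both axes point the same
    way. Axis dot products within ±0.5 of zero are labelled by the nearest
    class with an "oblique" warning.
    """
    ax_a, cen_a = cd_axis(host_a)
    ax_b, cen_b = cd_axis(host_b)
    angle = _fold_angle(ax_a, ax_b)
    delta = cen_b - cen_a
    dist = float(np.linalg.norm(delta))
    # decompose against the bisector of the two (sign-aligned) axes
    ref = ax_b if float(ax_a @ ax_b) >= 0 else -ax_b
    mean_axis = ax_a + ref
    mean_axis /= np.linalg.norm(mean_axis)
    axial = abs(float(delta @ mean_axis))
    lateral = float(np.linalg.norm(delta - (delta @ mean_axis) * mean_axis))
    if dist < 1e-9:
        d_hat = mean_axis
    else:
        d_hat = delta / dist
    s_a, s_b = float(ax_a @ d_hat), float(ax_b @ d_hat)
    if abs(s_a) < ORIENTATION_DOT or abs(s_b) < ORIENTATION_DOT:
        warnings.warn(
            f"oblique host pair (axis-offset dot products {s_a:.2f}, {s_b:.2f}); "
            "orientation label is nominal"
        )
    if s_a >= 0 and s_b < 0:
        orientation = "tail-to-tail"
    elif s_a < 0 and s_b >= 0:
        orientation = "head-to-head"
    else:
        orientation = "head-to-tail"
    return HostPairGeometry(angle, dist, lateral, axial, orientation)


def guest_orientation(guest_ring: np.ndarray, host: CDHost, rms_tol: float = 0.2) -> GuestOrientation:
    """Angle of a guest ring plane vs the host O4 plane, and penetration depth.

    ``guest_ring`` is an (n ≥ 5, 3) array of one ring's atom coordinates;
    depth is the signed distance of the ring centroid from the O4 plane
    along the host axis (positive toward the primary rim).
    """
    ring = np.asarray(guest_ring, dtype=float)
    if ring.shape[0] < 5:
        raise ValueError("need at least 5 ring atoms")
    ring_plane = fit_mean_plane(ring)
    if ring_plane.rms_dev > rms_tol:
        warnings.warn(f"guest ring is non-planar (rms {ring_plane.rms_dev:.3f} Å)")
    axis, _ = cd_axis(host)
    o4_plane = fit_mean_plane(host.o4_coords, orient=axis)
    angle = _fold_angle(ring_plane.normal, o4_plane.normal)
    depth = float((ring.mean(axis=0) - o4_plane.point) @ axis)
    return GuestOrientation(angle, depth)


def packing_mode(
    units: list[CDHost | np.ndarray],
    stacking_axis: np.ndarray,
) -> PackingMode:
    """Classify the stacking of successive complex units along an axis.

    ``units`` are the stacked units in stacking order, given either as
    annotated hosts (their O4 centroids are used) or as centroid coordinates.
    The successive shift is the component of the centroid–centroid vector
    perpendicular to the stacking direction; shifts ≤ 3.2 Å count as the
    channel (CH) packing mode observed for dimeric cyclodextrin structures.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 successive units")
    axis = np.asarray(stacking_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cents, axes = [], []
    for u in units:
        if isinstance(u, CDHost):
            a, c = cd_axis(u)
            cents.append(c)
            axes.append(a)
        else:
            cents.append(np.asarray(u, dtype=float))
    shifts = []
    for c0, c1 in zip(cents[:-1], cents[1:]):
        delta = c1 - c0
        perp = delta - (delta @ axis) * axis
        shifts.append(float(np.linalg.norm(perp)))
    shift = max(shifts)
    cell_angle = _fold_angle(axes[0], axis) if axes else math.nan
    return PackingMode(shift, cell_angle, "CH" if shift <= CH_SHIFT_MAX else "other")


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _element(sym: str) -> str:
    return sym.strip().upper()[:1]


def _attached_hydrogens(structure: CrystalStructure, coords: np.ndarray) -> dict[int, list[int]]:
    h_idx = [i for i, a in enumerate(structure.atoms) if _element(a.element) == "H"]
    heavy = [i for i, a in enumerate(structure.atoms) if _element(a.element) != "H"]
    out: dict[int, list[int]] = {i: [] for i in heavy}
    if not h_idx or not heavy:
        return out
    tree = cKDTree(coords[heavy])
    for h in h_idx:
        dist, j = tree.query(coords[h])
        if dist < 1.3:  # X-H covalent bond
            out[heavy[j]].append(h)
    return out


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = float(np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
    return math.degrees(math.acos(cosang))


def _with_symmetry_mates(structure: CrystalStructure, reach: float) -> CrystalStructure:
    base = structure.to_cartesian()
    if structure.cell is None or not structure.symops:
        return base
    pieces = [base]
    tree = cKDTree(base.coords)
    for op in structure.symops:
        for shift in np.ndindex(3, 3, 3):
            sh = np.array(shift) - 1
            if op.is_identity and not sh.any():
                continue
            mate = expand_symmetry(structure, op, sh).to_cartesian()
            near = tree.query_ball_point(mate.coords, reach)
            keep = [i for i, hits in enumerate(near) if hits]
            if keep:
                piece = mate.copy()
                piece.atoms = [piece.atoms[i] for i in keep]
                pieces.append(piece)
    merged = CrystalStructure()
    merged.cell = base.cell
    for k, piece in enumerate(pieces):
        for a in piece.atoms:
            b = np.array(a.coords)
            merged.atoms.append(
                type(a)(f"{a.label}#{k}" if k else a.label, a.element, b, a.occupancy, a.residue_id, a.alt_site)
            )
    return merged


def find_hbonds(
    structure: CrystalStructure,
    criteria: ContactCriteria | None = None,
    include_symmetry: bool = False,
) -> list[Contact]:
    """Geometric hydrogen-bond detection.

    O/N donors and acceptors are paired when d(D···A) ≤ 3.4 Å (inclusive).
    When a donor hydrogen is modelled the H···A distance (≤ 2.7 Å) and the
    D–H···A angle (≥ 120°) are additionally required; without modelled H
    (e.g. water in the deposited structures) the distance criterion alone
    decides. With ``include_symmetry`` the search also covers
    symmetry-expanded neighbours.
    """
    crit = criteria or ContactCriteria()
    st = (
        _with_symmetry_mates(structure, crit.hbond_da_max)
        if include_symmetry
        else structure.to_cartesian()
    )
    coords = st.coords
    hydro = _attached_hydrogens(st, coords)
    cand = [i for i, a in enumerate(st.atoms) if _element(a.element) in set(crit.donors) | set(crit.acceptors)]
    contacts: list[Contact] = []
    seen: set[tuple[int, int]] = set()
    if not cand:
        return contacts
    tree = cKDTree(coords[cand])
    for ii, jj in tree.query_pairs(crit.hbond_da_max + 1e-9):
        i, j = cand[ii], cand[jj]
        d_da = float(np.linalg.norm(coords[i] - coords[j]))
        if d_da < 2.0:  # covalently bonded, not an H-bond
            continue
        for donor, acceptor in ((i, j), (j, i)):
            if _element(st.atoms[donor].element) not in crit.donors:
                continue
            if _element(st.atoms[acceptor].element) not in crit.acceptors:
                continue
            hs = hydro.get(donor, [])
            if hs:
                best = None
                for h in hs:
                    d_ha = float(np.linalg.norm(coords[h] - coords[acceptor]))
                    ang = _angle(coords[donor], coords[h], coords[acceptor])
                    if d_ha <= crit.hbond_ha_max and ang >= crit.hbond_dha_min:
                        if best is None or d_ha < best[0]:
                            best = (d_ha, ang)
                if best is None:
                    continue
                d_ha, ang = best
            else:
                d_ha = ang = None
            key = (min(i, j), max(i, j))
            if key in seen:
                break
            seen.add(key)
            contacts.append(
                Contact(
                    f"{_element(st.atoms[donor].element)}-H...{_element(st.atoms[acceptor].element)}",
                    st.atoms[donor].label,
                    st.atoms[acceptor].label,
                    d_da,
                    d_ha,
                    ang,
                )
            )
            break
    return contacts


def find_close_contacts(
    structure: CrystalStructure,
    kinds: tuple[str, ...] = ("C-H...O", "H...H"),
    criteria: ContactCriteria | None = None,
) -> list[Contact]:
    """Weak (closed-shell) contacts: C–H···O and H···H.

    C–H···O requires a modelled hydrogen with H···O ≤ 2.9 Å and a C–H···O
    angle ≥ 110°; H···H pairs are reported at ≤ 2.4 Å (twice the hydrogen
    van der Waals radius). Each unordered pair appears once.
    """
    crit = criteria or ContactCriteria()
    st = structure.to_cartesian()
    coords = st.coords
    atoms = st.atoms
    h_idx = [i for i, a in enumerate(atoms) if _element(a.element) == "H"]
    contacts: list[Contact] = []
    hydro = _attached_hydrogens(st, coords)
    parent = {h: heavy for heavy, hs in hydro.items() for h in hs}
    if "H...H" in kinds and len(h_idx) >= 2:
        tree = cKDTree(coords[h_idx])
        for ii, jj in sorted(tree.query_pairs(crit.hh_max + 1e-9)):
            i, j = h_idx[ii], h_idx[jj]
            pi, pj = parent.get(i), parent.get(j)
            if pi is not None and pj is not None:
                if pi == pj:  # geminal pair, not a contact
                    continue
                if float(np.linalg.norm(coords[pi] - coords[pj])) < BOND_CUTOFF:
                    continue  # vicinal (parents bonded)
            d = float(np.linalg.norm(coords[i] - coords[j]))
            contacts.append(Contact("H...H", atoms[i].label, atoms[j].label, d, d))
    if "C-H...O" in kinds and h_idx:
        o_idx = [i for i, a in enumerate(atoms) if _element(a.element) == "O"]
        if o_idx:
            o_tree = cKDTree(coords[o_idx])
            for c, hs in hydro.items():
                if _element(atoms[c].element) != "C":
                    continue
                for h in hs:
                    for k in o_tree.query_ball_point(coords[h], crit.ch_o_ha_max + 1e-9):
                        o = o_idx[k]
                        if float(np.linalg.norm(coords[c] - coords[o])) < BOND_CUTOFF:
                            continue  # oxygen bonded to the donor carbon
                        d_ha = float(np.linalg.norm(coords[h] - coords[o]))
                        ang = _angle(coords[c], coords[h], coords[o])
                        if ang >= crit.ch_o_dha_min:
                            contacts.append(
                                Contact(
                                    "C-H...O",
                                    atoms[c].label,
                                    atoms[o].label,
                                    float(np.linalg.norm(coords[c] - coords[o])),
                                    d_ha,
                                    ang,
                                )
                            )
    # deduplicate unordered pairs
    out, seen = [], set()
    for c in contacts:
        key = (c.kind, frozenset((c.donor, c.acceptor)))
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out
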