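"""Reading, writing and annotating crystal structures and trajectories.

This module is the substrate for every geometric analysis in the package:
it parses small-molecule CIF and PDB files (via :mod:`gemmi`), converts
between fractional and Cartesian coordinates, applies crystallographic
symmetry operators, and identifies cyclodextrin macrocycles in a structure,
assigning each atom its chemical role (C1..C6, O2..O6, substituents).

Coordinate convention
---------------------
Internally everything is Cartesian angstroms; fractional coordinates are
kept only as read, until :meth:`CrystalStructure.to_cartesian` is called.
Orthogonalization follows the standard crystallographic convention
(*a* along *x*, *b* in the *xy* plane), as implemented by gemmi.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "UnitCell",
    "SymOp",
    "CrystalStructure",
    "CDHost",
    "Trajectory",
    "read_structure",
    "frac_to_cart",
    "cart_to_frac",
    "expand_symmetry",
    "annotate_cd",
    "read_trajectory",
    "write_trajectory",
    "write_structure",
    "match_deposit",
]

#: maximum heavy-atom distance regarded as a covalent bond (Å)
BOND_CUTOFF = 1.8


@dataclass
class Atom:
    """A single atom site.

    ``occupancy`` is the crystallographic site-occupancy factor (sof);
    disordered entities (e.g. a guest over two half-occupied sites) carry an
    ``alt_site`` tag so that descriptors can be computed per site rather than
    occupancy-averaged.
    """

    label: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    residue_id: int = 0
    alt_site: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.label!r}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.label!r}: element symbol is empty")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"atom {self.label!r}: occupancy {self.occupancy} not in (0, 1]")


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit-cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("unit-cell angles must lie in (0, 180) degrees")
        if self.volume <= 1e-9:
            raise ValueError("degenerate unit cell (zero volume)")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(max(arg, 0.0))

    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 fractional→Cartesian matrix (a along x, b in the xy plane)."""
        return np.array(self._gemmi().orth.mat.tolist(), dtype=float)

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.array(self._gemmi().frac.mat.tolist(), dtype=float)


def frac_to_cart(cell: UnitCell, frac: np.ndarray) -> np.ndarray:
    """Fractional → Cartesian (Å); accepts a 3-vector or an (n, 3) array."""
    frac = np.asarray(frac, dtype=float)
    return frac @ cell.orth_matrix.T


def cart_to_frac(cell: UnitCell, cart: np.ndarray) -> np.ndarray:
    cart = np.asarray(cart, dtype=float)
    return cart @ cell.frac_matrix.T


class SymOp:
    """Crystallographic symmetry operator with exact rational translation.

    Translations are stored as :class:`fractions.Fraction` so that repeated
    application cannot drift (screw-axis components are twelfths).
    """

    def __init__(self, rotation, translation, triplet: str | None = None):
        self.rotation = np.asarray(rotation, dtype=int)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        det = int(round(np.linalg.det(self.rotation)))
        if det not in (1, -1):
            raise ValueError(f"rotation determinant {det} not ±1")
        self.translation = tuple(Fraction(t).limit_denominator(12) for t in translation)
        self.triplet = triplet or self._make_triplet()

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        op = gemmi.Op(triplet)
        rot = np.array(op.rot, dtype=int)
        if np.any(rot % gemmi.Op.DEN):
            raise ValueError(f"non-integer rotation in symmetry operator {triplet!r}")
        rotation = rot // gemmi.Op.DEN
        translation = [Fraction(t, gemmi.Op.DEN) for t in op.tran]
        return cls(rotation, translation, triplet=op.triplet())

    def _make_triplet(self) -> str:
        op = gemmi.Op()
        op.rot = [[int(v) * gemmi.Op.DEN for v in row] for row in self.rotation]
        op.tran = [int(t * gemmi.Op.DEN) for t in self.translation]
        return op.triplet()

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.rotation, np.eye(3, dtype=int)) and all(
            t == 0 for t in self.translation
        )

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (3-vector or (n, 3))."""
        frac = np.asarray(frac, dtype=float)
        tran = np.array([float(t) for t in self.translation])
        return frac @ self.rotation.T.astype(float) + tran

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SymOp)
            and np.array_equal(self.rotation, other.rotation)
            and self.translation == other.translation
        )

    def __repr__(self) -> str:
        return f"SymOp({self.triplet!r})"


IDENTITY_OP = SymOp.from_triplet("x,y,z")


@dataclass
class CrystalStructure:
    """Atoms + optional unit cell and symmetry; the substrate of all geometry."""

    atoms: list[Atom] = field(default_factory=list)
    cell: UnitCell | None = None
    symops: list[SymOp] = field(default_factory=list)
    space_group: str = ""
    fractional: bool = False

    def __post_init__(self) -> None:
        if self.fractional and self.cell is None:
            raise ValueError("fractional coordinates require a unit cell")
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.residue_id, a.alt_site, a.label)
            if key in seen:
                raise ValueError(f"duplicate atom label {a.label!r} in residue {a.residue_id}")
            seen.add(key)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row

    def to_cartesian(self) -> "CrystalStructure":
        """Return a copy with Cartesian coordinates (no-op if already Cartesian)."""
        if not self.fractional:
            return self.copy()
        out = self.copy()
        out.set_coords(frac_to_cart(self.cell, self.coords))
        out.fractional = False
        return out

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            atoms=[replace(a, coords=a.coords.copy()) for a in self.atoms],
            cell=self.cell,
            symops=list(self.symops),
            space_group=self.space_group,
            fractional=self.fractional,
        )

    def select(self, predicate) -> "CrystalStructure":
        out = self.copy()
        out.atoms = [a for a in out.atoms if predicate(a)]
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom set (Å, ps per frame)."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    atoms: list[Atom]
    timestep: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError("frame atom count does not match atom metadata")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# File reading
# ---------------------------------------------------------------------------

_CIF_SYMOP_TAGS = (
    "_symmetry_equiv_pos_as_xyz",
    "_space_group_symop_operation_xyz",
)


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".cif":
        return "CIF"
    if suffix in (".pdb", ".ent"):
        return "PDB"
    if suffix == ".xyz":
        return "XYZ"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_structure(path, format: str | None = None) -> CrystalStructure:
    """Read a crystal structure from a small-molecule CIF or a PDB file.

    CIF atoms are returned with fractional coordinates as read (conversion
    deferred); PDB atoms are Cartesian.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or _guess_format(path)).upper()
    if fmt == "CIF":
        return _read_cif(path)
    if fmt == "PDB":
        return _read_pdb(path)
    raise ValueError(f"unsupported structure format {fmt!r}")


def _read_cif(path: Path) -> CrystalStructure:
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed CIF {path.name}: {exc}") from exc
    block = doc.sole_block()

    def number(tag: str) -> float | None:
        raw = block.find_value(tag)
        return None if raw is None else gemmi.cif.as_number(raw)

    cell = None
    lengths = [number(f"_cell_length_{x}") for x in "abc"]
    if all(v is not None for v in lengths):
        angles = [number(f"_cell_angle_{x}") or 90.0 for x in ("alpha", "beta", "gamma")]
        cell = UnitCell(*lengths, *angles)

    symops: list[SymOp] = []
    for tag in _CIF_SYMOP_TAGS:
        col = block.find_loop(tag)
        values = list(col) if col else ([block.find_value(tag)] if block.find_value(tag) else [])
        for raw in values:
            if raw:
                symops.append(SymOp.from_triplet(gemmi.cif.as_string(raw)))
        if symops:
            break

    space_group = ""
    for tag in ("_space_group_name_H-M_alt", "_symmetry_space_group_name_H-M"):
        raw = block.find_value(tag)
        if raw:
            space_group = gemmi.cif.as_string(raw)
            break

    table = block.find(
        "_atom_site_",
        ["label", "?type_symbol", "fract_x", "fract_y", "fract_z", "?occupancy", "?disorder_group"],
    )
    atoms: list[Atom] = []
    for row in table:
        label = gemmi.cif.as_string(row["_atom_site_label"])
        element = (
            gemmi.cif.as_string(row["_atom_site_type_symbol"])
            if row.has(1)
            else _element_from_label(label)
        )
        coords = [gemmi.cif.as_number(row[f"_atom_site_fract_{x}"]) for x in "xyz"]
        occ = gemmi.cif.as_number(row["_atom_site_occupancy"]) if row.has(5) else 1.0
        if occ is None or math.isnan(occ):
            occ = 1.0
        alt = None
        if row.has(6):
            g = gemmi.cif.as_string(row["_atom_site_disorder_group"])
            alt = g if g not in (".", "?", "") else None
        atoms.append(Atom(label, element.strip(), coords, occupancy=occ, alt_site=alt))
    if atoms and cell is None:
        raise ValueError(f"{path.name}: fractional _atom_site coordinates but no _cell_ tags")
    return CrystalStructure(atoms, cell=cell, symops=symops, space_group=space_group, fractional=bool(atoms))


def _element_from_label(label: str) -> str:
    head = "".join(c for c in label if c.isalpha())[:2]
    if len(head) == 2 and head[1].islower() and head.capitalize() in ("Cl", "Br", "Na"):
        return head.capitalize()
    return head[:1].upper() if head else "X"


def _read_pdb(path: Path) -> CrystalStructure:
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB {path.name}: {exc}") from exc
    cell = None
    # gemmi reports a dummy 1x1x1 cell when the PDB has no CRYST1 record
    if st.cell is not None and st.cell.volume > 2.0:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    atoms: list[Atom] = []
    if len(st) == 0:
        raise ValueError(f"{path.name}: no models")
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                atoms.append(
                    Atom(
                        atom.name,
                        atom.element.name or _element_from_label(atom.name),
                        [atom.pos.x, atom.pos.y, atom.pos.z],
                        occupancy=min(max(atom.occ, 1e-6), 1.0),
                        residue_id=residue.seqid.num,
                        alt_site=atom.altloc or None,
                    )
                )
    return CrystalStructure(atoms, cell=cell, fractional=False)


# ---------------------------------------------------------------------------
# Symmetry expansion
# ---------------------------------------------------------------------------

def expand_symmetry(
    structure: CrystalStructure,
    op: SymOp,
    cell_shift: Sequence[int] = (0, 0, 0),
    tag: str | None = None,
) -> CrystalStructure:
    """Return a copy of *structure* with *op* (plus a lattice shift) applied.

    The input must carry (or be convertible to) fractional coordinates.
    Atom labels are suffixed with a symmetry tag so expanded copies remain
    distinguishable from the asymmetric unit.
    """
    if structure.cell is None:
        raise ValueError("expand_symmetry requires a unit cell")
    if structure.symops and all(op != known for known in structure.symops):
        warnings.warn(f"operator {op.triplet!r} is not in the structure's symmetry list")
    frac = (
        structure.coords
        if structure.fractional
        else cart_to_frac(structure.cell, structure.coords)
    )
    new_frac = op.apply(frac) + np.asarray(cell_shift, dtype=float)
    suffix = tag if tag is not None else f"@{op.triplet}+{tuple(int(s) for s in cell_shift)}"
    out = structure.copy()
    out.fractional = True
    out.set_coords(new_frac)
    for a in out.atoms:
        a.label = a.label + suffix
    return out


# ---------------------------------------------------------------------------
# Cyclodextrin annotation
# ---------------------------------------------------------------------------

RING_ROLES = ("O5", "C1", "C2", "C3", "C4", "C5")
CORE_ROLES = RING_ROLES + ("O4",)
ROLE_NAMES = ("C1", "C2", "C3", "C4", "C5", "C6", "O2", "O3", "O4", "O5", "O6")


@dataclass
class CDHost:
    """An annotated cyclodextrin macrocycle: 7 glucose residues in ring order.

    ``residues[n]`` maps role names (C1..C6, O2..O6 and substituent slots
    such as ``CM6`` for an O6-methyl carbon) to atom indices into
    ``structure.atoms``. Ring connectivity convention: C1 of residue *n+1*
    is glycosidically bonded to O4 of residue *n*.
    """

    structure: CrystalStructure
    residues: list[dict[str, int]]
    substitution: str = "native"

    def __post_init__(self) -> None:
        if len(self.residues) != 7:
            raise ValueError(f"a cyclodextrin host needs exactly 7 residues, got {len(self.residues)}")
        for n, roles in enumerate(self.residues):
            missing = [r for r in ("C1", "C2", "C3", "C4", "C5", "O4", "O5") if r not in roles]
            if missing:
                raise ValueError(f"residue {n}: missing role atoms {missing}")

    def role_coords(self, role: str) -> np.ndarray:
        """Coordinates of one role across the 7 residues, ring order, (7, 3)."""
        idx = [roles[role] for roles in self.residues]
        return np.array([self.structure.atoms[i].coords for i in idx])

    def residue_coords(self, n: int, roles: Iterable[str]) -> np.ndarray:
        res = self.residues[n % 7]
        out = []
        for role in roles:
            if role not in res:
                raise KeyError(f"residue {n}: role {role!r} not annotated")
            out.append(self.structure.atoms[res[role]].coords)
        return np.array(out)

    @property
    def o4_coords(self) -> np.ndarray:
        return self.role_coords("O4")

    @property
    def atom_indices(self) -> list[int]:
        return sorted(i for roles in self.residues for i in roles.values())


def _bond_pairs(coords: np.ndarray, cutoff: float = BOND_CUTOFF) -> np.ndarray:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs if len(pairs) else np.empty((0, 2), dtype=int)


def annotate_cd(structure: CrystalStructure, scheme: str = "auto") -> list[CDHost]:
    """Identify cyclodextrin macrocycles and assign per-atom chemical roles.

    ``scheme``:
      * ``"labels"`` — trust atom labels of the form C1..C6/O2..O6 grouped by
        ``residue_id`` (the builder's convention and suffix-style CIF dialects);
      * ``"connectivity"`` — ignore labels, detect pyranose rings from the
        covalent-bond graph and walk the glycosidic linkage;
      * ``"auto"`` — labels when they parse, connectivity otherwise.
    """
    st = structure.to_cartesian()
    if scheme not in ("auto", "labels", "connectivity"):
        raise ValueError(f"unknown annotation scheme {scheme!r}")
    if scheme in ("auto", "labels"):
        try:
            return _annotate_by_labels(st, structure)
        except ValueError:
            if scheme == "labels":
                raise
    return _annotate_by_connectivity(st, structure)


def _base_role(label: str) -> str | None:
    lab = label.split("@")[0].upper()
    if len(lab) >= 2 and lab[0] in "CO" and lab[1] in "123456" and (len(lab) == 2 or not lab[2:].isdigit()):
        role = lab[:2]
        if role in ROLE_NAMES or lab[:3] in ("CM2", "CM3", "CM6"):
            return lab[:3] if lab[:2] == "CM" else role
    if lab[:2] == "CM" and len(lab) >= 3 and lab[2] in "236":
        return lab[:3]
    if lab[:2] == "CH" or lab[:2] == "OH":  # hydroxypropyl chain atoms
        return lab[:3]
    return None


def _annotate_by_labels(st: CrystalStructure, parent: CrystalStructure) -> list[CDHost]:
    groups: dict[int, dict[str, int]] = {}
    for i, atom in enumerate(st.atoms):
        role = _base_role(atom.label)
        if role is None:
            continue
        groups.setdefault(atom.residue_id, {})
        if role in groups[atom.residue_id]:
            raise ValueError(
                f"ambiguous labels: role {role!r} duplicated in residue {atom.residue_id}; "
                "use scheme='connectivity' or an explicit labelling"
            )
        groups[atom.residue_id][role] = i
    glucose = {
        rid: roles
        for rid, roles in groups.items()
        if all(r in roles for r in ("C1", "C2", "C3", "C4", "C5", "O4", "O5"))
    }
    if not glucose:
        raise ValueError("no labelled glucose residues found")
    return _assemble_hosts(st, parent, glucose)


def _assemble_hosts(
    st: CrystalStructure, parent: CrystalStructure, glucose: dict[int, dict[str, int]]
) -> list[CDHost]:
    coords = st.coords
    rids = sorted(glucose)
    # glycosidic adjacency: O4(r) bonded to C1(s). Ring ordering tolerates
    # strained geometries (distorted macrocycles stretch this link); the
    # nearest C1 of another residue decides, capped well below the ~4 A
    # separation of non-bonded neighbours.
    succ: dict[int, int] = {}
    for r in rids:
        o4 = coords[glucose[r]["O4"]]
        cand = [
            (float(np.linalg.norm(o4 - coords[glucose[s]["C1"]])), s)
            for s in rids
            if s != r
        ]
        if cand:
            dist, s = min(cand)
            if dist < 2.5:
                succ[r] = s
    hosts: list[CDHost] = []
    seen: set[int] = set()
    for r in rids:
        if r in seen or r not in succ:
            continue
        ring = [r]
        cur = r
        while succ.get(cur) is not None and succ[cur] not in ring:
            cur = succ[cur]
            ring.append(cur)
        if succ.get(cur) != r:
            continue  # open chain, not a macrocycle
        seen.update(ring)
        if len(ring) != 7:
            raise ValueError(f"candidate macrocycle has {len(ring)} glucose units, expected 7")
        residues = [dict(glucose[rid]) for rid in ring]
        hosts.append(CDHost(parent, residues, substitution=_infer_substitution(st, residues)))
    if not hosts:
        raise ValueError("no closed 7-residue macrocycle found")
    return hosts


def _infer_substitution(st: CrystalStructure, residues: list[dict[str, int]]) -> str:
    coords = st.coords
    carbons = [
        i for i, a in enumerate(st.atoms) if a.element.upper().startswith("C")
    ]
    tree = cKDTree(coords[carbons]) if carbons else None
    ring_atoms = {
        i for roles in residues for role, i in roles.items() if role in ROLE_NAMES
    }

    def substituent_chain(o_idx: int) -> int:
        """Number of carbons in the substituent attached to this oxygen."""
        if tree is None:
            return 0
        hits = tree.query_ball_point(coords[o_idx], BOND_CUTOFF)
        ext = [carbons[h] for h in hits if carbons[h] not in ring_atoms]
        if not ext:
            return 0
        # walk the carbon chain away from the oxygen
        chain = set(ext)
        frontier = list(ext)
        while frontier:
            nxt = []
            for c in frontier:
                for h in tree.query_ball_point(coords[c], BOND_CUTOFF):
                    cc = carbons[h]
                    if cc not in chain and cc not in ring_atoms:
                        chain.add(cc)
                        nxt.append(cc)
            frontier = nxt
        return len(chain)

    methylated = {"O2": 0, "O3": 0, "O6": 0}
    hydroxypropyl = 0
    for roles in residues:
        for o in ("O2", "O3", "O6"):
            if o not in roles:
                continue
            n_c = substituent_chain(roles[o])
            if n_c == 1:
                methylated[o] += 1
            elif n_c >= 3:
                hydroxypropyl += 1
    if hydroxypropyl:
        return f"hydroxypropyl({hydroxypropyl})"
    if methylated["O2"] >= 6 and methylated["O6"] >= 6 and methylated["O3"] >= 6:
        return "permethyl"
    if methylated["O2"] >= 6 and methylated["O6"] >= 6:
        return "2,6-di-O-methyl"
    if any(methylated.values()):
        return "methylated(partial)"
    return "native"


def _annotate_by_connectivity(st: CrystalStructure, parent: CrystalStructure) -> list[CDHost]:
    coords = st.coords
    heavy = [i for i, a in enumerate(st.atoms) if a.element.upper() != "H"]
    g = nx.Graph()
    g.add_nodes_from(heavy)
    sub = coords[heavy]
    for i, j in _bond_pairs(sub):
        g.add_edge(heavy[i], heavy[j])

    elem = lambda i: st.atoms[i].element.upper()[:1]
    glucose: dict[int, dict[str, int]] = {}
    rid = 0
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) != 6:
            continue
        oxy = [i for i in cycle if elem(i) == "O"]
        if len(oxy) != 1:
            continue
        o5 = oxy[0]
        ring_c = [i for i in cycle if i != o5]
        nbrs_o5 = [i for i in g[o5] if i in ring_c]
        if len(nbrs_o5) != 2:
            continue
        # C1 is the ring carbon on O5 that also carries an exocyclic oxygen
        # bridging to another ring (the glycosidic O4 of the neighbour).
        def exo_oxygens(c):
            return [j for j in g[c] if elem(j) == "O" and j != o5 and j not in cycle]

        c1 = None
        for cand in nbrs_o5:
            if exo_oxygens(cand):
                c1 = cand
                break
        if c1 is None:
            continue
        c5 = [i for i in nbrs_o5 if i != c1][0]
        # walk C1 -> C2 -> C3 -> C4 around the ring (away from O5)
        order = [c1]
        prev, cur = o5, c1
        while len(order) < 5:
            nxt = [i for i in g[cur] if i in cycle and i != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            order.append(cur)
        if len(order) != 5 or order[-1] != c5:
            continue
        roles = {"O5": o5, "C1": order[0], "C2": order[1], "C3": order[2], "C4": order[3], "C5": c5}
        for cn, on in (("C2", "O2"), ("C3", "O3"), ("C4", "O4")):
            exo = exo_oxygens(roles[cn])
            if exo:
                roles[on] = exo[0]
        # C6/O6 off C5
        exo_c = [j for j in g[c5] if elem(j) == "C" and j not in cycle]
        if exo_c:
            roles["C6"] = exo_c[0]
            o6 = [j for j in g[exo_c[0]] if elem(j) == "O"]
            if o6:
                roles["O6"] = o6[0]
        if "O4" not in roles:
            continue
        glucose[rid] = roles
        rid += 1
    if not glucose:
        raise ValueError("connectivity annotation found no glucose rings")
    return _assemble_hosts(st, parent, glucose)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(path, format: str | None = None, timestep: float = 1.0) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ trajectory.

    Neither text format carries a timestep; it is supplied by the caller
    (ps per frame, default 1.0).
    """
    path = Path(path)
    fmt = (format or _guess_format(path)).upper()
    if fmt == "XYZ":
        return _read_xyz(path, timestep)
    if fmt == "PDB":
        return _read_pdb_traj(path, timestep)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def _read_xyz(path: Path, timestep: float) -> Trajectory:
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    atoms: list[Atom] | None = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path.name}: bad atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path.name}: truncated frame {frame_no}")
        symbols, xyz = [], []
        for ln in block:
            parts = ln.split()
            symbols.append(parts[0])
            xyz.append([float(x) for x in parts[1:4]])
        if atoms is None:
            atoms = [Atom(f"{s}{k + 1}", s, p) for k, (s, p) in enumerate(zip(symbols, xyz))]
        elif len(symbols) != len(atoms):
            raise ValueError(
                f"{path.name}: frame {frame_no} has {len(symbols)} atoms, expected {len(atoms)}"
            )
        frames.append(np.array(xyz))
        i += 2 + n
        frame_no += 1
    if atoms is None:
        raise ValueError(f"{path.name}: empty trajectory")
    return Trajectory(np.array(frames), atoms, timestep)


def _read_pdb_traj(path: Path, timestep: float) -> Trajectory:
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path.name}: no MODEL records")
    frames = []
    atoms: list[Atom] | None = None
    for m, model in enumerate(st):
        meta, xyz = [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    meta.append(
                        Atom(
                            atom.name,
                            atom.element.name or _element_from_label(atom.name),
                            [atom.pos.x, atom.pos.y, atom.pos.z],
                            residue_id=residue.seqid.num,
                        )
                    )
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        if atoms is None:
            atoms = meta
        elif len(meta) != len(atoms):
            raise ValueError(f"{path.name}: model {m} has {len(meta)} atoms, expected {len(atoms)}")
        frames.append(np.array(xyz))
    return Trajectory(np.array(frames), atoms, timestep)


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or _guess_format(path)).upper()
    if fmt == "XYZ":
        with path.open("w") as fh:
            for k in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\nframe {k}\n")
                for atom, (x, y, z) in zip(traj.atoms, traj.frames[k]):
                    fh.write(f"{atom.element:<3s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
        return
    if fmt == "PDB":
        with path.open("w") as fh:
            for k in range(traj.n_frames):
                fh.write(f"MODEL     {k + 1:4d}\n")
                _write_pdb_atoms(fh, traj.atoms, traj.frames[k])
                fh.write("ENDMDL\n")
            fh.write("END\n")
        return
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def _write_pdb_atoms(fh, atoms: list[Atom], xyz: np.ndarray) -> None:
    for i, (atom, (x, y, z)) in enumerate(zip(atoms, xyz), start=1):
        name = atom.label[:4]
        fh.write(
            f"HETATM{i % 100000:5d} {name:<4s} CD  A{atom.residue_id % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}  0.00          "
            f"{atom.element[:2]:>2s}\n"
        )


def write_structure(structure: CrystalStructure, path) -> None:
    """Write Cartesian coordinates as a single-model PDB file."""
    st = structure.to_cartesian()
    path = Path(path)
    with path.open("w") as fh:
        if st.cell is not None:
            c = st.cell
            fh.write(
                f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
                f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} P 1           1\n"
            )
        _write_pdb_atoms(fh, st.atoms, st.coords)
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Deposit disambiguation
# ---------------------------------------------------------------------------

def match_deposit(structure: CrystalStructure, reference_cells: dict[str, UnitCell]) -> str:
    """Name the complex whose published unit cell best matches *structure*.

    Matching is by relative deviation of cell lengths plus absolute deviation
    of cell angles; used to disambiguate deposited CIFs whose identifiers do
    not state which complex they contain.
    """
    if structure.cell is None:
        raise ValueError("structure has no unit cell")
    c = structure.cell

    def score(ref: UnitCell) -> float:
        rel = sum(
            abs(getattr(c, k) - getattr(ref, k)) / getattr(ref, k) for k in ("a", "b", "c")
        )
        ang = sum(abs(getattr(c, k) - getattr(ref, k)) for k in ("alpha", "beta", "gamma"))
        return rel + ang / 90.0

    return min(reference_cells, key=lambda name: score(reference_cells[name]))
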