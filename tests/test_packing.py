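"""Host-pair arrangement, guest orientation, packing mode and contacts."""

import itertools

import numpy as np
import pytest

from conftest import random_rigid_transform, transform_structure
from cycloscope.packing_interactions import (
    Contact,
    ContactCriteria,
    find_close_contacts,
    find_hbonds,
    guest_orientation,
    host_pair_geometry,
    packing_mode,
)
from cycloscope.structure_io import Atom, CrystalStructure, annotate_cd
from cycloscope.synthetic_data import (
    CDBuildSpec,
    ComplexBuildSpec,
    GuestSpec,
    build_complex,
)

ORIENTATIONS = ("head-to-tail", "tail-to-tail", "head-to-head")


class TestHostPair:
    @pytest.mark.parametrize("orientation", ORIENTATIONS)
    def test_constructed_orientation_recovered(self, orientation):
        st, _ = build_complex(ComplexBuildSpec(orientation=orientation, axial_shift=8.0))
        hp = host_pair_geometry(*annotate_cd(st))
        assert hp.orientation == orientation
        assert hp.interplanar_angle == pytest.approx(0.0, abs=1e-6)
        assert hp.lateral_offset == pytest.approx(0.0, abs=1e-6)

    def test_axial_and_lateral_decomposition(self):
        st, _ = build_complex(
            ComplexBuildSpec(orientation="head-to-tail", axial_shift=8.0, lateral_offset=2.0)
        )
        hp = host_pair_geometry(*annotate_cd(st))
        assert hp.axial_shift == pytest.approx(8.0, abs=1e-6)
        assert hp.lateral_offset == pytest.approx(2.0, abs=1e-6)
        assert hp.centroid_distance**2 == pytest.approx(
            hp.axial_shift**2 + hp.lateral_offset**2, abs=1e-6
        )

    def test_interplanar_angle_recovered(self):
        st, _ = build_complex(ComplexBuildSpec(interplanar_angle=5.0))
        hp = host_pair_geometry(*annotate_cd(st))
        assert hp.interplanar_angle == pytest.approx(5.0, abs=0.01)

    def test_argument_order_invariance(self):
        st, _ = build_complex(ComplexBuildSpec(orientation="tail-to-tail"))
        a, b = annotate_cd(st)
        hp1, hp2 = host_pair_geometry(a, b), host_pair_geometry(b, a)
        assert hp1.orientation == hp2.orientation
        assert hp1.interplanar_angle == pytest.approx(hp2.interplanar_angle, abs=1e-9)
        assert hp1.centroid_distance == pytest.approx(hp2.centroid_distance, abs=1e-9)
        assert hp1.axial_shift == pytest.approx(hp2.axial_shift, abs=1e-9)

    def test_orientation_grid_all_correct(self):
        """27-case grid: orientation x axial shift x uniform residue tilt."""
        for orientation, shift, tilt in itertools.product(
            ORIENTATIONS, (7.5, 8.0, 9.0), (0.0, 5.0, 10.0)
        ):
            spec = ComplexBuildSpec(
                hosts=(CDBuildSpec(tilts=(tilt,) * 7), CDBuildSpec(tilts=(tilt,) * 7)),
                orientation=orientation,
                axial_shift=shift,
            )
            st, _ = build_complex(spec)
            hp = host_pair_geometry(*annotate_cd(st))
            assert hp.orientation == orientation, (orientation, shift, tilt)

    def test_rigid_motion_invariance(self):
        st, _ = build_complex(ComplexBuildSpec(orientation="tail-to-tail", lateral_offset=1.5))
        ref = host_pair_geometry(*annotate_cd(st))
        rng = np.random.default_rng(77)
        for _ in range(10):
            rot, trans = random_rigid_transform(rng)
            moved = transform_structure(st, rot, trans)
            hp = host_pair_geometry(*annotate_cd(moved))
            assert hp.orientation == ref.orientation
            assert hp.interplanar_angle == pytest.approx(ref.interplanar_angle, abs=1e-6)
            assert hp.axial_shift == pytest.approx(ref.axial_shift, abs=1e-9)
            assert hp.lateral_offset == pytest.approx(ref.lateral_offset, abs=1e-9)


class TestGuestOrientation:
    def test_parallel_ring_on_plane(self, ideal_host):
        ang = 2 * np.pi * np.arange(6) / 6
        ring = np.column_stack([1.4 * np.cos(ang), 1.4 * np.sin(ang), np.zeros(6)])
        go = guest_orientation(ring, ideal_host)
        assert go.ring_plane_angle == pytest.approx(0.0, abs=1e-9)
        assert go.penetration_depth == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_ring_above_plane(self, ideal_host):
        ang = 2 * np.pi * np.arange(6) / 6
        ring = np.column_stack([1.4 * np.cos(ang), np.zeros(6), 2.0 + 1.4 * np.sin(ang)])
        go = guest_orientation(ring, ideal_host)
        assert go.ring_plane_angle == pytest.approx(90.0, abs=1e-9)
        assert go.penetration_depth == pytest.approx(2.0, abs=1e-9)

    def test_builder_guest_angle_closure(self, guest_complex):
        st, truth = guest_complex
        host = annotate_cd(st)[0]
        ring = st.coords[truth["ring_a_indices"]]
        go = guest_orientation(ring, host)
        assert go.ring_plane_angle == pytest.approx(truth["ring_a_angle"], abs=0.1)

    def test_nonplanar_ring_warns(self, ideal_host):
        rng = np.random.default_rng(0)
        ring = rng.normal(scale=1.5, size=(6, 3))
        with pytest.warns(UserWarning, match="non-planar"):
            guest_orientation(ring, ideal_host)


class TestPackingMode:
    def test_coaxial_stack_is_channel(self):
        cents = [np.array([0.0, 0.0, z]) for z in (0, 8, 16)]
        pm = packing_mode(cents, [0, 0, 1])
        assert pm.successive_shift == pytest.approx(0.0)
        assert pm.mode == "CH"

    def test_three_angstrom_offset_still_channel(self):
        cents = [np.array([0, 0, 0.0]), np.array([3.0, 0, 8.0])]
        pm = packing_mode(cents, [0, 0, 1])
        assert pm.successive_shift == pytest.approx(3.0)
        assert pm.mode == "CH"

    def test_six_angstrom_offset_is_other(self):
        cents = [np.array([0, 0, 0.0]), np.array([6.0, 0, 8.0])]
        assert packing_mode(cents, [0, 0, 1]).mode == "other"

    def test_host_stack_with_axis_angle(self):
        st, _ = build_complex(ComplexBuildSpec(orientation="head-to-tail"))
        hosts = annotate_cd(st)
        pm = packing_mode(hosts, [0, 0, 1])
        assert pm.mode == "CH"
        assert pm.axis_cell_angle == pytest.approx(0.0, abs=1e-6)

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            packing_mode([np.zeros(3)], [0, 0, 1])


def _water_pair(d, with_h=False, angle=180.0):
    atoms = [Atom("OW1", "O", [0, 0, 0]), Atom("OW2", "O", [d, 0, 0], residue_id=2)]
    if with_h:
        # donor H on OW1 pointing at OW2 for angle 180
        x = 0.96 * np.cos(np.radians(180.0 - angle))
        atoms.append(Atom("HW1", "H", [0.96 if angle == 180 else x, 0.96 * np.sin(np.radians(180 - angle)), 0]))
    return CrystalStructure(atoms, fractional=False)


class TestHBonds:
    def test_ideal_geometry_found(self):
        contacts = find_hbonds(_water_pair(2.8, with_h=True))
        assert len(contacts) == 1
        c = contacts[0]
        assert c.d_DA == pytest.approx(2.8)
        assert c.angle_DHA == pytest.approx(180.0, abs=1e-6)

    def test_too_far_apart_empty(self):
        assert find_hbonds(_water_pair(4.0)) == []

    def test_boundary_inclusive(self):
        assert len(find_hbonds(_water_pair(3.4))) == 1

    def test_hydrogen_free_mode(self):
        # no H modelled (deposited waters): distance criterion alone decides
        contacts = find_hbonds(_water_pair(2.8, with_h=False))
        assert len(contacts) == 1
        assert contacts[0].d_HA is None

    def test_bad_angle_rejected_when_h_present(self):
        # both donors carry hydrogens pointing away: geometry fails on each
        st = CrystalStructure(
            [
                Atom("OW1", "O", [0, 0, 0]),
                Atom("HW1", "H", [-0.68, 0.68, 0]),
                Atom("OW2", "O", [2.8, 0, 0], residue_id=2),
                Atom("HW2", "H", [3.48, 0.68, 0], residue_id=2),
            ],
            fractional=False,
        )
        assert find_hbonds(st) == []

    def test_pairs_deduplicated(self):
        contacts = find_hbonds(_water_pair(2.8))
        keys = {frozenset((c.donor, c.acceptor)) for c in contacts}
        assert len(keys) == len(contacts)


class TestCloseContacts:
    def test_hh_within_cutoff(self):
        st = CrystalStructure(
            [Atom("H1", "H", [0, 0, 0]), Atom("H2", "H", [2.2, 0, 0], residue_id=2)],
            fractional=False,
        )
        found = find_close_contacts(st, kinds=("H...H",))
        assert len(found) == 1 and found[0].d_DA == pytest.approx(2.2)

    def test_hh_outside_cutoff(self):
        st = CrystalStructure(
            [Atom("H1", "H", [0, 0, 0]), Atom("H2", "H", [2.6, 0, 0], residue_id=2)],
            fractional=False,
        )
        assert find_close_contacts(st, kinds=("H...H",)) == []

    def test_geminal_pair_excluded(self):
        # two H on the same carbon are 1.8 A apart but not a contact
        st = CrystalStructure(
            [
                Atom("C1", "C", [0, 0, 0]),
                Atom("H1", "H", [1.09, 0, 0]),
                Atom("H2", "H", [-0.36, 1.03, 0]),
            ],
            fractional=False,
        )
        assert find_close_contacts(st, kinds=("H...H",)) == []

    def test_ch_o_contact_reported_with_geometry(self):
        # linear C-H...O with H...O = 2.5 A
        st = CrystalStructure(
            [
                Atom("C1", "C", [0, 0, 0]),
                Atom("H1", "H", [1.09, 0, 0]),
                Atom("O1", "O", [1.09 + 2.5, 0, 0], residue_id=2),
            ],
            fractional=False,
        )
        found = find_close_contacts(st, kinds=("C-H...O",))
        assert len(found) == 1
        assert found[0].d_HA == pytest.approx(2.5)
        assert found[0].angle_DHA == pytest.approx(180.0, abs=1e-6)

    def test_ch_o_bad_angle_rejected(self):
        st = CrystalStructure(
            [
                Atom("C1", "C", [0, 0, 0]),
                Atom("H1", "H", [1.09, 0, 0]),
                Atom("O1", "O", [1.09, 2.5, 0], residue_id=2),  # ~90 deg
            ],
            fractional=False,
        )
        assert find_close_contacts(st, kinds=("C-H...O",)) == []
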