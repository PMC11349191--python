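"""Role assignment, hydrogen placement, and geometric H-bond detection."""

import math

import numpy as np
import pytest

from aquabridge.hbond import (
    Criteria,
    assign_roles,
    attached_hydrogens,
    detect_hbond,
    hbond_graph,
    place_missing_hydrogens,
)
from aquabridge.structio import select

from conftest import mini_structure, water


def two_waters(donor_h_dir, acceptor_pos, d_oh=0.96):
    """Donor water with one explicit H, plus a bare-O acceptor water."""
    h = np.asarray(donor_h_dir, float)
    h = d_oh * h / np.linalg.norm(h)
    specs1, c1 = water(1, (0.0, 0.0, 0.0), tuple(h))
    specs2, c2 = water(2, tuple(acceptor_pos))
    return mini_structure(specs1 + specs2, [c1 + c2])


class TestAssignRoles:
    def test_water_oxygen_is_both(self):
        s = mini_structure(*_wrap(water(1, (0, 0, 0))))
        assert assign_roles(s)[0] == "both"

    @pytest.mark.parametrize(
        "resname,name,element,expected",
        [
            ("ALA", "O", "O", "acceptor"),
            ("ALA", "N", "N", "donor"),
            ("SER", "OG", "O", "both"),
            ("LYS", "NZ", "N", "donor"),
            ("ASP", "OD1", "O", "acceptor"),
            ("HIS", "ND1", "N", "both"),
            ("MET", "SD", "S", "acceptor"),
        ],
    )
    def test_residue_chemistry_table(self, resname, name, element, expected):
        s = mini_structure(
            [(name, element, resname, 1, "A")], np.zeros((1, 1, 3))
        )
        assert assign_roles(s)[0] == expected

    def test_unknown_residue_gets_both(self, caplog):
        s = mini_structure(
            [("O1", "O", "XYZ", 1, "A")], np.zeros((1, 1, 3))
        )
        assert assign_roles(s)[0] == "both"

    def test_hydrogen_and_carbon_get_none(self):
        s = mini_structure(
            [("CA", "C", "GLY", 1, "A"), ("H", "H", "GLY", 1, "A")],
            np.zeros((1, 2, 3)),
        )
        assert assign_roles(s) == ["none", "none"]


def _wrap(sw):
    specs, coords = sw
    return specs, [coords]


class TestDetectHbond:
    crit = Criteria(distDA=3.5, angleWW=(100.0, 180.0))

    def test_ideal_linear_geometry_accepted(self):
        s = two_waters((1, 0, 0), (2.8, 0, 0))
        hb = detect_hbond(s, 0, 2, criteria=self.crit)
        assert hb is not None
        assert hb.distance_DA == pytest.approx(2.8)
        assert hb.angle_DHA == pytest.approx(180.0)

    def test_distance_violation_rejected(self):
        s = two_waters((1, 0, 0), (4.0, 0, 0))
        assert detect_hbond(s, 0, 2, criteria=self.crit) is None

    def test_angle_violation_rejected(self):
        # H at (0,1,0): angle at H is 70.35 deg, outside [100, 180]
        s = two_waters((0, 1, 0), (2.8, 0, 0), d_oh=1.0)
        assert detect_hbond(s, 0, 2, criteria=self.crit) is None
        v1 = np.array([0, -1.0, 0])
        v2 = np.array([2.8, -1.0, 0])
        ang = math.degrees(
            math.acos(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2))
        )
        assert ang == pytest.approx(70.35, abs=0.05)

    def test_angle_free_mode_distance_only(self):
        s = two_waters((0, 1, 0), (2.8, 0, 0))
        crit = Criteria(angle_mode="angle-free")
        hb = detect_hbond(s, 0, 2, criteria=crit)
        assert hb is not None and hb.angle_DHA is None

    def test_same_residue_rejected(self):
        specs, coords = water(1, (0, 0, 0), (0.96, 0, 0))
        specs2, coords2 = water(1, (2.8, 0, 0))
        s = mini_structure(specs + specs2, [coords + coords2])
        assert detect_hbond(s, 0, 2, criteria=self.crit) is None

    def test_missing_hydrogen_rejected_not_raised(self):
        specs, coords = water(1, (0, 0, 0))
        specs2, coords2 = water(2, (2.8, 0, 0))
        s = mini_structure(specs + specs2, [coords + coords2])
        crit = Criteria(angle_mode="with-hydrogens")
        assert detect_hbond(s, 0, 1, criteria=crit) is None

    def test_rotatable_donor_falls_back_to_distance(self):
        s = mini_structure(
            [("OG", "O", "SER", 1, "A")] + water(2, (2.8, 0, 0))[0],
            [[(0, 0, 0), (2.8, 0, 0)]],
        )
        crit = Criteria(angle_mode="with-hydrogens")
        hb = detect_hbond(s, 0, 1, criteria=crit)
        assert hb is not None and hb.hydrogen_atom is None

    def test_water_pair_directions_independent(self):
        # W1 donates to W2 (linear H), W2 has no H: only one direction
        s = two_waters((1, 0, 0), (2.8, 0, 0))
        crit = Criteria(angle_mode="with-hydrogens", angleWW=(100, 180))
        assert detect_hbond(s, 0, 2, criteria=crit) is not None
        assert detect_hbond(s, 2, 0, criteria=crit) is None


class TestPlaceMissingHydrogens:
    def test_bare_water_gets_ideal_geometry(self):
        s = mini_structure(*_wrap(water(1, (1.0, 2.0, 3.0))))
        s2 = place_missing_hydrogens(s)
        assert [a.name for a in s2.atoms] == ["O", "H1", "H2"]
        o, h1, h2 = s2.coords[0]
        assert np.linalg.norm(h1 - o) == pytest.approx(0.96, abs=1e-6)
        assert np.linalg.norm(h2 - o) == pytest.approx(0.96, abs=1e-6)
        v1, v2 = h1 - o, h2 - o
        ang = math.degrees(
            math.acos(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2))
        )
        assert ang == pytest.approx(104.5, abs=0.1)

    def test_idempotent_on_protonated_water(self):
        s = mini_structure(
            *_wrap(water(1, (0, 0, 0), (0.96, 0, 0), (-0.24, 0.93, 0)))
        )
        s2 = place_missing_hydrogens(s)
        assert s2.n_atoms == s.n_atoms

    def test_first_hydrogen_points_at_nearby_acceptor(self):
        specs = [("O", "O", "ALA", 1, "A")] + water(2, (2.8, 0, 0))[0]
        s = mini_structure(specs, [[(0.0, 0.0, 0.0), (2.8, 0.0, 0.0)]])
        s2 = place_missing_hydrogens(s)
        o = s2.coords[0][1]
        h1 = s2.coords[0][2]
        toward = np.array([0.0, 0.0, 0.0]) - o
        placed = h1 - o
        ang = math.degrees(
            math.acos(
                toward @ placed / np.linalg.norm(toward) / np.linalg.norm(placed)
            )
        )
        assert ang < 15.0

    def test_protein_donors_left_alone(self):
        s = mini_structure(
            [("N", "N", "GLY", 1, "A")], np.zeros((1, 1, 3))
        )
        assert place_missing_hydrogens(s) is s


class TestHbondGraph:
    def test_valence_cap_on_star(self):
        # one bare water surrounded by 5 equidistant Ser OG acceptors:
        # angle-free, the water could donate 5 bonds; cap keeps 2
        specs, coords = water(1, (0, 0, 0))
        for i in range(5):
            ang = 2 * math.pi * i / 5
            specs.append(("OG", "O", "SER", i + 2, "A"))
            coords.append((2.8 * math.cos(ang), 2.8 * math.sin(ang), 0.0))
        s = mini_structure(specs, [coords])
        bonds = hbond_graph(s, criteria=Criteria(angle_mode="angle-free"))
        donated = [b for b in bonds if b.donor_atom == 0]
        accepted = [b for b in bonds if b.acceptor_atom == 0]
        assert len(donated) <= 2 and len(accepted) <= 2

    def test_no_waters_leaves_protein_protein_only(self):
        s = mini_structure(
            [("N", "N", "GLY", 1, "A"), ("O", "O", "GLY", 2, "A")],
            [[(0, 0, 0), (2.9, 0, 0)]],
        )
        bonds = hbond_graph(s, criteria=Criteria(angle_mode="angle-free"))
        assert all(b.kind == "protein-protein" for b in bonds)

    def test_grid_equals_brute_force(self, rng):
        crit = Criteria(
            angle_mode="angle-free",
            max_donated_per_water=99,
            max_accepted_per_water=99,
        )
        for _ in range(10):
            n = int(rng.integers(10, 50))
            specs, coords = [], []
            for j in range(n):
                sw, cw = water(j + 1, tuple(rng.uniform(0, 12, 3)))
                specs += sw
                coords += cw
            s = mini_structure(specs, [coords])
            got = {
                (b.donor_atom, b.acceptor_atom)
                for b in hbond_graph(s, criteria=crit)
            }
            expect = set()
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    hb = detect_hbond(s, i, j, criteria=crit)
                    if hb:
                        expect.add((i, j))
            assert got == expect

    def test_monotonic_in_distDA(self, rng):
        for _ in range(5):
            specs, coords = [], []
            for j in range(30):
                sw, cw = water(j + 1, tuple(rng.uniform(0, 10, 3)))
                specs += sw
                coords += cw
            s = mini_structure(specs, [coords])
            kw = dict(
                angle_mode="angle-free",
                max_donated_per_water=99,
                max_accepted_per_water=99,
            )
            tight = hbond_graph(s, criteria=Criteria(distDA=3.0, **kw))
            loose = hbond_graph(s, criteria=Criteria(distDA=3.6, **kw))
            tight_set = {(b.donor_atom, b.acceptor_atom) for b in tight}
            loose_set = {(b.donor_atom, b.acceptor_atom) for b in loose}
            assert tight_set <= loose_set

    def test_angle_free_superset_of_with_hydrogens(self, rng):
        count_strict = 0
        for _ in range(200):
            h_dir = rng.normal(size=3)
            acc = rng.normal(size=3)
            acc = acc / np.linalg.norm(acc) * rng.uniform(2.0, 4.5)
            s = two_waters(h_dir, acc)
            with_h = detect_hbond(
                s, 0, 2, criteria=Criteria(angle_mode="with-hydrogens")
            )
            free = detect_hbond(
                s, 0, 2, criteria=Criteria(angle_mode="angle-free")
            )
            if with_h is not None:
                assert free is not None
            if free is not None and with_h is None:
                count_strict += 1
        assert count_strict > 0

    def test_auto_mode_resolution(self):
        bare = mini_structure(*_wrap(water(1, (0, 0, 0))))
        protonated = mini_structure(
            *_wrap(water(1, (0, 0, 0), (0.96, 0, 0)))
        )
        assert Criteria().resolve(bare).angle_mode == "angle-free"
        assert (
            Criteria().resolve(protonated).angle_mode == "with-hydrogens"
        )


class TestCriteriaValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"distDA": 0.0},
            {"distWR": -1.0},
            {"maxDepth": 0},
            {"anglePDWA": (120.0, 100.0)},
            {"angleWW": (0.0, 270.0)},
            {"angle_mode": "sideways"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Criteria(**kwargs)


def test_attached_hydrogens_by_distance():
    specs, coords = water(1, (0, 0, 0), (0.96, 0, 0), (-0.24, 0.93, 0))
    specs2, coords2 = water(2, (5, 0, 0))
    s = mini_structure(specs + specs2, [coords + coords2])
    h_map = attached_hydrogens(s)
    assert h_map == {0: [1, 2]}
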