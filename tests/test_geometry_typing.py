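import math

import numpy as np
import pytest

from boddkit import (
    assign,
    build_connectivity,
    build_environment_graph,
    expand_instruction,
    graph_hash,
    lone_directions,
    make_fixture,
)
from boddkit.geometry_typing import (
    LONE_LOBE_COUNTS,
    TETRAHEDRAL_ANGLE,
    deserialize_graph,
    graph_similarity,
    read_database,
    serialize_graph,
    write_database,
)
from boddkit.model import (
    AtomSite,
    BedeInstruction,
    Cell,
    CrystalStructure,
    LoneInstruction,
    ModelError,
)
from boddkit.data import FORM_FACTORS
from boddkit.synthetic import archetype_database


def two_carbons(distance):
    cell = Cell(10.0, 10.0, 10.0)
    atoms = [
        AtomSite("C1", "C", np.array([0.3, 0.5, 0.5]), u_iso=0.03),
        AtomSite("C2", "C", np.array([0.3 + distance / 10.0, 0.5, 0.5]), u_iso=0.03),
    ]
    return CrystalStructure(cell=cell, atoms=atoms, sfac_table={"C": FORM_FACTORS["C"]})


class TestConnectivity:
    def test_standard_cc_bond(self):
        table = build_connectivity(two_carbons(1.54))
        assert table.bonded("C1", "C2")
        assert table.bond_length("C1", "C2") == pytest.approx(1.54, abs=0.01)

    def test_three_angstrom_not_bonded(self):
        assert not build_connectivity(two_carbons(3.0)).bonded("C1", "C2")

    def test_ethane_each_carbon_four_neighbors(self, ethane):
        table = build_connectivity(ethane.structure)
        assert len(table.neighbors_of("C1")) == 4
        assert len(table.neighbors_of("C2")) == 4

    def test_bond_across_cell_boundary(self):
        cell = Cell(8.0, 8.0, 8.0)
        atoms = [
            AtomSite("C1", "C", np.array([0.02, 0.5, 0.5]), u_iso=0.03),
            AtomSite("C2", "C", np.array([0.98 + 1.54 / 8.0 - 1.0 + 1.0, 0.5, 0.5]), u_iso=0.03),
        ]
        # C2 sits at x=0.98+...: wrap so nearest image of C2 is 1.54 A away
        atoms[1].xyz = np.array([(0.02 - 1.54 / 8.0) % 1.0, 0.5, 0.5])
        structure = CrystalStructure(cell=cell, atoms=atoms, sfac_table={"C": FORM_FACTORS["C"]})
        assert build_connectivity(structure).bonded("C1", "C2")


class TestLoneDirections:
    root = np.zeros(3)

    def test_counts_per_code(self):
        assert LONE_LOBE_COUNTS == {1: 1, 2: 2, 3: 3, 6: 2, 7: 2, 9: 2, 12: 12, 15: 1}

    def test_m1_c3v_antiparallel_to_bond_sum(self):
        theta = math.radians(109.47)
        nbs = [
            [math.sin(theta) * math.cos(p), math.sin(theta) * math.sin(p), math.cos(theta)]
            for p in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
        ]
        # bonds point below the xy plane, so the lone pair points up +z
        (v,) = lone_directions(1, self.root, nbs)
        assert np.allclose(v, [0.0, 0.0, 1.0], atol=1e-10)

    def test_m2_angle_between_lobes(self):
        nbs = [[1.0, 1.0, 0.0], [-1.0, 1.0, 0.0]]
        v1, v2 = lone_directions(2, self.root, nbs, angle=109.5)
        assert math.degrees(math.acos(np.dot(v1, v2))) == pytest.approx(109.5, abs=1e-8)
        # both lobes point away from the bonds
        assert v1[1] < 0 and v2[1] < 0

    def test_m3_cone_angle_from_bond(self):
        u = np.array([0.0, 0.0, 1.0])
        dirs = lone_directions(3, self.root, [u], angle=109.5)
        assert len(dirs) == 3
        for v in dirs:
            assert math.degrees(math.acos(np.dot(v, u))) == pytest.approx(109.5, abs=1e-8)
        azimuths = sorted(math.degrees(math.atan2(v[1], v[0])) % 360 for v in dirs)
        gaps = np.diff(azimuths + [azimuths[0] + 360.0])
        assert np.allclose(gaps, 120.0, atol=1e-8)

    def test_m6_antiparallel_plane_normals(self):
        nbs = [[1.0, 0.3, 0.0], [-0.7, 0.8, 0.0]]
        v1, v2 = lone_directions(6, self.root, nbs)
        assert np.allclose(v1, -v2, atol=1e-12)
        for nb in nbs:
            assert abs(np.dot(v1, nb / np.linalg.norm(nb))) < 1e-12

    def test_m7_out_of_plane(self):
        nb = [1.21, 0.0, 0.0]
        second = [2.0, 1.0, 0.0]
        v1, v2 = lone_directions(7, self.root, [nb], angle=180.0, second_shell=second)
        assert np.allclose(v1, [0, 0, 1], atol=1e-10) or np.allclose(v1, [0, 0, -1], atol=1e-10)
        assert np.allclose(v1, -v2, atol=1e-12)

    def test_m9_in_plane(self):
        nb = [1.21, 0.0, 0.0]
        second = [2.0, 1.0, 0.0]
        v1, v2 = lone_directions(9, self.root, [nb], angle=120.0, second_shell=second)
        for v in (v1, v2):
            assert abs(v[2]) < 1e-12  # stays in the molecular plane
            # 60 degrees off the reverse bond direction
            assert math.degrees(math.acos(np.dot(v, [-1.0, 0.0, 0.0]))) == pytest.approx(
                60.0, abs=1e-8
            )

    def test_m12_cone_and_interleaved_half_sets(self):
        u = np.array([0.0, 0.0, 1.0])
        dirs = lone_directions(12, self.root, [u])
        assert len(dirs) == 12
        for v in dirs:
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)
            # cone half-angle: tetrahedral complement about the reverse bond
            assert math.degrees(math.acos(np.dot(v, -u))) == pytest.approx(
                180.0 - TETRAHEDRAL_ANGLE, abs=1e-8
            )
        azimuths = sorted(math.degrees(math.atan2(v[1], v[0])) % 360 for v in dirs)
        gaps = np.diff(azimuths + [azimuths[0] + 360.0])
        assert np.allclose(gaps, 30.0, atol=1e-8)
        # the two three-fold (methyl-position) subsets are rotated by 60 deg
        trio_a = [a for a in azimuths if min(a % 120.0, 120.0 - a % 120.0) < 1e-6]
        trio_b = [a for a in azimuths if min((a - 60.0) % 120.0, 120.0 - (a - 60.0) % 120.0) < 1e-6]
        assert len(trio_a) == 3 and len(trio_b) == 3

    def test_m15_five_bonds(self):
        nbs = [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]]
        (v,) = lone_directions(15, self.root, nbs)
        assert np.allclose(v, [0, 0, -1], atol=1e-12)

    def test_unit_norm_property(self):
        rng = np.random.default_rng(11)
        for m in (1, 2, 3, 6, 7, 9, 12, 15):
            n_nb = {1: 3, 2: 2, 3: 1, 6: 2, 7: 1, 9: 1, 12: 1, 15: 4}[m]
            nbs = rng.normal(size=(n_nb, 3))
            kw = {}
            if m in (2, 3, 7, 9):
                kw["angle"] = 109.5
            if m in (7, 9, 12, 3):
                kw["second_shell"] = rng.normal(size=3)
            dirs = lone_directions(m, self.root, nbs, **kw)
            assert len(dirs) == LONE_LOBE_COUNTS[m]
            for v in dirs:
                assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_neighbor_count_mismatch_names_code(self):
        with pytest.raises(ModelError, match="m=1"):
            lone_directions(1, self.root, [[1, 0, 0]])

    def test_collinear_neighbors_degenerate(self):
        with pytest.raises(ModelError, match="collinear"):
            lone_directions(6, self.root, [[1, 0, 0], [-1, 0, 0]])

    def test_second_shell_required(self):
        with pytest.raises(ModelError, match="second-shell"):
            lone_directions(7, self.root, [[1, 0, 0]], angle=180.0)


class TestExpandInstruction:
    def test_bede_two_lobes(self, carbonyl, carbonyl_conn):
        instr = BedeInstruction("C1", "O1", 0.5, 0.28, 1.0, 0.8)
        lobes = expand_instruction(instr, carbonyl.structure, carbonyl_conn)
        assert len(lobes) == 2
        amps = sorted(g.amplitude for g in lobes)
        assert amps == pytest.approx([-0.28, 0.28])
        minus = min(lobes, key=lambda g: g.amplitude)
        assert np.allclose(minus.center_frac, carbonyl.structure.atom("C1").xyz)
        plus = max(lobes, key=lambda g: g.amplitude)
        d = carbonyl.structure.cell.distance(
            carbonyl.structure.atom("C1").xyz, plus.center_frac
        )
        assert d == pytest.approx(0.5, abs=1e-9)

    def test_lone_m2_three_lobes_minus_2a(self, water, water_conn):
        instr = LoneInstruction(2, "O1", 0.18, 1.0, 0.9, 0.35, 109.5)
        lobes = expand_instruction(instr, water.structure, water_conn)
        assert len(lobes) == 3
        assert min(g.amplitude for g in lobes) == pytest.approx(-2 * 0.18)

    def test_lone_m12_thirteen_lobes_minus_6a(self, carbonyl, carbonyl_conn):
        instr = LoneInstruction(12, "O1", 0.1, 1.0, 0.9, 0.35)
        lobes = expand_instruction(instr, carbonyl.structure, carbonyl_conn)
        assert len(lobes) == 13
        positive = [g for g in lobes if g.amplitude > 0]
        assert len(positive) == 12
        for g in positive:
            assert g.amplitude == pytest.approx(0.5 * 0.1)  # half occupancy
        comp = min(lobes, key=lambda g: g.amplitude)
        assert comp.amplitude == pytest.approx(-6 * 0.1)

    def test_balance_invariant_all_fixtures(self):
        for name in ("ethane_p1", "carbonyl_p1", "water_p1", "methylamine_p1", "mixed_metal_p1"):
            fx = make_fixture(name, seed=3)
            conn = build_connectivity(fx.structure)
            for instr in fx.instructions:
                lobes = expand_instruction(instr, fx.structure, conn)
                assert sum(g.amplitude for g in lobes) == pytest.approx(0.0, abs=1e-14)

    def test_unknown_atom_label(self, water, water_conn):
        with pytest.raises(ModelError, match="Q9"):
            expand_instruction(
                BedeInstruction("O1", "Q9", 0.5, 0.1, 1.0, 1.0), water.structure, water_conn
            )


class TestEnvironmentGraph:
    def test_isolated_atom_single_node(self):
        structure = two_carbons(4.0)
        table = build_connectivity(structure)
        g = build_environment_graph("C1", table, structure)
        assert g.number_of_nodes() == 1
        assert g.nodes["C1"]["color"] == (0.0, 0.0, 0.0, 1.0)

    def test_methylamine_n_two_shell_graph(self, methylamine):
        # hand enumeration: N1 root; shell 1 = C1, H4, H5; shell 2 = H1..H3
        conn = build_connectivity(methylamine.structure)
        g = build_environment_graph("N1", conn, methylamine.structure)
        assert g.number_of_nodes() == 7
        assert g.number_of_edges() == 6
        levels = sorted(g.nodes[n]["level"] for n in g.nodes)
        assert levels == [0, 1, 1, 1, 2, 2, 2]

    def test_root_green_is_bond_length_sum(self, ethane):
        conn = build_connectivity(ethane.structure)
        g = build_environment_graph("C1", conn, ethane.structure)
        expected = sum(conn.bond_length("C1", nb) for nb in conn.neighbors_of("C1"))
        assert g.nodes["C1"]["color"][1] == pytest.approx(expected)
        assert expected == pytest.approx(1.54 + 3 * 1.09, abs=0.05)

    def test_level1_blue_one_level2_blue_two(self, methylamine):
        conn = build_connectivity(methylamine.structure)
        g = build_environment_graph("N1", conn, methylamine.structure)
        for n in g.nodes:
            lvl = g.nodes[n]["level"]
            assert g.nodes[n]["color"][2] == float(lvl)


class TestGraphHash:
    def test_relabel_invariance_randomized(self, methylamine):
        conn = build_connectivity(methylamine.structure)
        g = build_environment_graph("N1", conn, methylamine.structure)
        base = graph_hash(g)
        serial = serialize_graph(g)
        rng = np.random.default_rng(17)
        import networkx as nx

        for _ in range(100):
            gg = deserialize_graph(serial)
            perm = rng.permutation(gg.number_of_nodes())
            relabeled = nx.relabel_nodes(gg, {i: int(p) for i, p in enumerate(perm)})
            assert graph_hash(relabeled) == base

    def test_differing_level2_changes_digest(self, methylamine, ethane):
        conn_m = build_connectivity(methylamine.structure)
        conn_e = build_connectivity(ethane.structure)
        g1 = build_environment_graph("C1", conn_m, methylamine.structure)
        g2 = build_environment_graph("C1", conn_e, ethane.structure)
        assert graph_hash(g1) != graph_hash(g2)

    def test_quantization_bucket_stability(self, water):
        conn = build_connectivity(water.structure)
        g = build_environment_graph("O1", conn, water.structure)
        # snap colors onto bucket centers so a 0.001 A perturbation provably
        # stays inside its 0.01 A bucket
        g1 = g.copy()
        for n in g1.nodes:
            r, gr, b, a = g1.nodes[n]["color"]
            g1.nodes[n]["color"] = (round(r, 2), round(gr, 2), b, a)
        base = graph_hash(g1, quantization=0.01)
        g2 = g1.copy()
        for n in g2.nodes:
            r, gr, b, a = g2.nodes[n]["color"]
            g2.nodes[n]["color"] = (r + 0.001, gr + 0.001, b, a)
        assert graph_hash(g2, quantization=0.01) == base

    def test_serialization_round_trip(self, water):
        conn = build_connectivity(water.structure)
        g = build_environment_graph("O1", conn, water.structure)
        back = deserialize_graph(serialize_graph(g))
        assert graph_hash(back) == graph_hash(g)


class TestDatabaseAndAssign:
    def test_database_text_round_trip(self, water):
        records = archetype_database(water)
        text = write_database(records)
        back = read_database(text)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.invariom_name == b.invariom_name
            assert a.inner_hash == b.inner_hash
            assert b.verify_hash()
            assert len(a.parameters) == len(b.parameters)

    def test_all_atoms_covered_zero_fallbacks(self, water):
        records = archetype_database(water)
        instructions, report = assign(water.structure, records)
        assert report["n_fallback"] == 0
        assert report["n_iam_only"] == 0
        assert len(instructions) == len(water.instructions)

    def test_missing_archetype_falls_back_to_nearest(self, water, methylamine):
        # database from methylamine only: water O has no exact match but a
        # same-element candidate exists
        records = [
            r for r in archetype_database(methylamine) if r.root_element != "O"
        ]
        # graft an O record from a different environment (carbonyl O)
        carbonyl = make_fixture("carbonyl_p1", seed=1)
        records += [r for r in archetype_database(carbonyl) if r.root_element == "O"]
        _, report = assign(water.structure, records)
        entry = report["atoms"]["O1"]
        assert entry["status"] == "fallback"
        assert entry["record"] is not None
        assert 0.0 < entry["score"] < 1.0

    def test_metal_atom_iam_only(self, mixed_metal):
        records = archetype_database(mixed_metal)
        instructions, report = assign(mixed_metal.structure, records)
        assert report["atoms"]["Zn1"]["status"] == "iam_only"
        assert all(
            getattr(i, "atom1", getattr(i, "atom", None)) != "Zn1" for i in instructions
        )

    def test_similarity_self_is_one(self, water):
        conn = build_connectivity(water.structure)
        g = build_environment_graph("O1", conn, water.structure)
        assert graph_similarity(g, g) == pytest.approx(1.0)

    def test_empty_database_rejected(self, water):
        with pytest.raises(ModelError, match="empty"):
            assign(water.structure, [])
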