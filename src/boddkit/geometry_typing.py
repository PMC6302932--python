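"""Connectivity, lobe geometry, environment graphs and automatic assignment.

The geometric constructions mirror the way riding-hydrogen directions are
deduced from the other bonds of an atom: each lone-pair code ``m`` maps the
root atom's bonding environment to a fixed set of unit vectors. Atom typing
uses a two-shell colored environment graph whose canonical hash keys a small
archetype database of deformation-card templates.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .data import COVALENT_RADII
from .model import (
    BedeInstruction,
    CrystalStructure,
    Instruction,
    LoneInstruction,
    ModelError,
    PlacedGaussian,
)

__all__ = [
    "ConnectivityTable",
    "EnvironmentGraph",
    "ArchetypeRecord",
    "BedeTemplate",
    "LoneTemplate",
    "build_connectivity",
    "lone_directions",
    "expand_instruction",
    "expand_instructions",
    "build_environment_graph",
    "graph_hash",
    "graph_similarity",
    "assign",
    "serialize_graph",
    "deserialize_graph",
    "read_database",
    "write_database",
    "LONE_LOBE_COUNTS",
    "TETRAHEDRAL_ANGLE",
]

#: lobes placed on the geometry (excluding the compensating at-atom lobe)
LONE_LOBE_COUNTS = {1: 1, 2: 2, 3: 3, 6: 2, 7: 2, 9: 2, 12: 12, 15: 1}

#: number of bonded neighbors each geometry code expects
_NEIGHBOR_COUNTS = {1: (3, 3), 2: (2, 2), 3: (1, 1), 6: (2, 2),
                    7: (1, 1), 9: (1, 1), 12: (1, 1), 15: (4, 5)}

#: codes that need an atom bonded to the neighbor to fix a reference plane/azimuth
_SECOND_SHELL_REQUIRED = frozenset({7, 9})

TETRAHEDRAL_ANGLE = math.degrees(math.acos(-1.0 / 3.0))  # 109.471...


# ---------------------------------------------------------------------------
# connectivity


@dataclass
class ConnectivityTable:
    """Symmetric bond table with lengths in angstrom."""

    bonds: dict[frozenset, float] = field(default_factory=dict)
    neighbors: dict[str, list[str]] = field(default_factory=dict)

    def add_bond(self, a: str, b: str, length: float) -> None:
        key = frozenset((a, b))
        if key in self.bonds:
            return
        self.bonds[key] = length
        self.neighbors.setdefault(a, []).append(b)
        self.neighbors.setdefault(b, []).append(a)

    def bonded(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.bonds

    def bond_length(self, a: str, b: str) -> float:
        return self.bonds[frozenset((a, b))]

    def neighbors_of(self, label: str) -> list[str]:
        return list(self.neighbors.get(label, []))

    def bond_length_sum(self, label: str) -> float:
        return sum(self.bond_length(label, nb) for nb in self.neighbors.get(label, []))


def build_connectivity(
    structure: CrystalStructure,
    radii_table: Optional[dict[str, float]] = None,
    tolerance: float = 0.4,
) -> ConnectivityTable:
    """Bond two sites when their minimum-image distance is below the sum of
    covalent radii plus ``tolerance`` (angstrom), scanning symmetry copies so
    bonds across the cell boundary are found."""
    radii = radii_table or COVALENT_RADII
    table = ConnectivityTable()
    atoms = structure.atoms
    for atom in atoms:
        table.neighbors.setdefault(atom.label, [])
    for i, a in enumerate(atoms):
        for b in atoms[i + 1:]:
            ra = radii.get(a.element.capitalize())
            rb = radii.get(b.element.capitalize())
            if ra is None or rb is None:
                continue
            cutoff = ra + rb + tolerance
            best = math.inf
            for op in structure.symmetry_ops:
                d = structure.cell.min_image_distance(a.xyz, op.apply(b.xyz))
                best = min(best, d)
            if 0.1 < best < cutoff:
                table.add_bond(a.label, b.label, best)
    return table


# ---------------------------------------------------------------------------
# lobe geometry


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise ModelError("degenerate geometry: zero-length direction vector")
    return v / n


def _any_perpendicular(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    return _unit(trial - np.dot(trial, u) * u)


def lone_directions(
    m: int,
    root_xyz: Sequence[float],
    neighbor_xyz: Sequence[Sequence[float]],
    angle: Optional[float] = None,
    second_shell: Optional[Sequence[float]] = None,
) -> list[np.ndarray]:
    """Unit vectors (Cartesian) from the root atom toward each lobe position.

    m=1: one vector opposite the bond-vector sum of three neighbors.
    m=2: two vectors separated by ``angle`` in the plane through the bond
         bisector perpendicular to the two-bond plane.
    m=3: three staggered vectors at ``angle`` from the single bond.
    m=6: the two normals of the plane of two bonds (pi-density).
    m=7: two vectors tilted +-angle/2 out of the plane fixed by the bond and
         a second-shell atom (terminal pi-density; angle 180 gives the pure
         plane normals).
    m=9: like m=7 but tilted within the plane (in-plane lone pairs).
    m=12: twelve vectors on a cone about the reverse bond axis, 30 degrees
          apart in azimuth (two 60-degree-staggered half-sets).
    m=15: one vector opposite the bond-vector sum of 4-5 neighbors.
    """
    if m not in LONE_LOBE_COUNTS:
        raise ModelError(f"unsupported lone-pair geometry code m={m}")
    root = np.asarray(root_xyz, dtype=float)
    nbs = [np.asarray(p, dtype=float) for p in neighbor_xyz]
    lo, hi = _NEIGHBOR_COUNTS[m]
    if not lo <= len(nbs) <= hi:
        want = f"{lo}" if lo == hi else f"{lo}-{hi}"
        raise ModelError(
            f"m={m} expects {want} bonded neighbors, got {len(nbs)}"
        )
    if m in _SECOND_SHELL_REQUIRED and second_shell is None:
        raise ModelError(f"m={m} needs a second-shell atom to fix the reference plane")
    units = [_unit(nb - root) for nb in nbs]

    if m in (1, 15):
        return [_unit(-np.sum(units, axis=0))]

    if m == 2:
        u1, u2 = units
        cross = np.cross(u1, u2)
        if np.linalg.norm(cross) < 1e-8:
            raise ModelError("m=2: collinear neighbors cannot define a plane")
        bisector = _unit(-(u1 + u2))
        normal = _unit(cross)
        half = math.radians(angle) / 2.0
        return [
            _unit(bisector * math.cos(half) + sign * normal * math.sin(half))
            for sign in (+1.0, -1.0)
        ]

    if m == 3:
        u = units[0]
        theta = math.radians(angle)
        e1 = (
            _staggered_reference(u, root, nbs[0], second_shell)
            if second_shell is not None
            else _any_perpendicular(u)
        )
        e2 = np.cross(u, e1)
        out = []
        for k in range(3):
            phi = 2.0 * math.pi * k / 3.0
            e = e1 * math.cos(phi) + e2 * math.sin(phi)
            out.append(_unit(u * math.cos(theta) + e * math.sin(theta)))
        return out

    if m == 6:
        u1, u2 = units
        cross = np.cross(u1, u2)
        if np.linalg.norm(cross) < 1e-8:
            raise ModelError("m=6: collinear bonds cannot define a plane")
        n = _unit(cross)
        return [n, -n]

    if m in (7, 9):
        u = units[0]
        w = np.asarray(second_shell, dtype=float) - root
        w_in = w - np.dot(w, u) * u
        if np.linalg.norm(w_in) < 1e-8:
            raise ModelError(f"m={m}: second-shell atom collinear with the bond")
        w_in = _unit(w_in)
        normal = _unit(np.cross(u, w_in))
        tilt = normal if m == 7 else w_in
        half = math.radians(angle if angle is not None else 180.0) / 2.0
        return [
            _unit(-u * math.cos(half) + sign * tilt * math.sin(half))
            for sign in (+1.0, -1.0)
        ]

    if m == 12:
        u = units[0]
        axis = -u
        # cone half-angle: tetrahedral complement of the single bond
        psi = math.radians(180.0 - TETRAHEDRAL_ANGLE)
        e1 = (
            _staggered_reference(u, root, nbs[0], second_shell)
            if second_shell is not None
            else _any_perpendicular(axis)
        )
        e2 = np.cross(axis, e1)
        out = []
        for k in range(12):
            phi = math.radians(30.0 * k)
            e = e1 * math.cos(phi) + e2 * math.sin(phi)
            out.append(_unit(axis * math.cos(psi) + e * math.sin(psi)))
        return out

    raise AssertionError("unreachable")


def _staggered_reference(u, root, neighbor, second_shell) -> np.ndarray:
    """Azimuth reference anti-periplanar to a second-shell substituent."""
    w = np.asarray(second_shell, dtype=float) - np.asarray(neighbor, dtype=float)
    w_perp = w - np.dot(w, u) * u
    if np.linalg.norm(w_perp) < 1e-8:
        return _any_perpendicular(u)
    return _unit(-w_perp)


# ---------------------------------------------------------------------------
# instruction expansion


def _cart(structure: CrystalStructure, label: str) -> np.ndarray:
    return structure.cell.frac_to_cart(structure.atom(label).xyz)


def _nearest_image_cart(structure, from_label: str, to_label: str) -> np.ndarray:
    """Cartesian position of to_label's image nearest to from_label."""
    x_from = structure.atom(from_label).xyz
    x_to = structure.atom(to_label).xyz
    d = x_to - x_from
    d -= np.round(d)
    return structure.cell.frac_to_cart(x_from + d)


def _second_shell_position(structure, connectivity, root: str, neighbor: str):
    candidates = [
        nb for nb in connectivity.neighbors_of(neighbor) if nb != root
    ]
    if not candidates:
        return None
    # deterministic: prefer non-H, then lexicographic
    candidates.sort(key=lambda l: (structure.atom(l).element.capitalize() == "H", l))
    return _nearest_image_cart(structure, neighbor, candidates[0])


def expand_instruction(
    instr: Instruction,
    structure: CrystalStructure,
    connectivity: ConnectivityTable,
) -> list[PlacedGaussian]:
    """Expand one card into its placed lobes.

    The signed amplitudes (weighted by lobe occupancy) of every expansion sum
    to zero, so no instruction changes the model's electron count.
    """
    cell = structure.cell
    if isinstance(instr, BedeInstruction):
        for label in (instr.atom1, instr.atom2):
            try:
                structure.atom(label)
            except KeyError:
                raise ModelError(f"BEDE references unknown atom label {label!r}")
        x1 = structure.atom(instr.atom1).xyz
        c1 = cell.frac_to_cart(x1)
        c2 = _nearest_image_cart(structure, instr.atom1, instr.atom2)
        u = _unit(c2 - c1)
        center = cell.cart_to_frac(c1 + instr.r * u)
        origin = instr.to_card()
        return [
            PlacedGaussian(tuple(center), +instr.A, instr.B1, instr.atom1, origin),
            PlacedGaussian(tuple(x1), -instr.A, instr.B2, instr.atom1, origin),
        ]

    if isinstance(instr, LoneInstruction):
        try:
            root_atom = structure.atom(instr.atom)
        except KeyError:
            raise ModelError(f"LONE references unknown atom label {instr.atom!r}")
        nbs = connectivity.neighbors_of(instr.atom)
        root_c = cell.frac_to_cart(root_atom.xyz)
        nb_pos = [_nearest_image_cart(structure, instr.atom, nb) for nb in nbs]
        second = None
        if instr.m in (3, 7, 9, 12) and nbs:
            second = _second_shell_position(structure, connectivity, instr.atom, nbs[0])
        try:
            dirs = lone_directions(
                instr.m, root_c, nb_pos, angle=instr.angle, second_shell=second
            )
        except ModelError as exc:
            raise ModelError(f"LONE m={instr.m} on {instr.atom}: {exc}") from exc
        occ = 0.5 if instr.m == 12 else 1.0
        origin = instr.to_card()
        lobes = []
        for v in dirs:
            center = cell.cart_to_frac(root_c + instr.r * v)
            lobes.append(
                PlacedGaussian(tuple(center), occ * instr.A, instr.B1, instr.atom, origin)
            )
        total = occ * instr.A * len(dirs)
        lobes.append(
            PlacedGaussian(tuple(root_atom.xyz), -total, instr.B2, instr.atom, origin)
        )
        return lobes

    raise TypeError(f"not an instruction: {instr!r}")


def expand_instructions(
    instructions: Sequence[Instruction],
    structure: CrystalStructure,
    connectivity: Optional[ConnectivityTable] = None,
) -> list[PlacedGaussian]:
    if connectivity is None:
        connectivity = build_connectivity(structure)
    out: list[PlacedGaussian] = []
    for instr in instructions:
        out.extend(expand_instruction(instr, structure, connectivity))
    return out


# ---------------------------------------------------------------------------
# environment graphs

EnvironmentGraph = nx.Graph


def _level2_alpha() -> float:
    # the source table's level-2 alpha entry is ambiguous; fixed constant
    return 1.0


def build_environment_graph(
    root_label: str,
    connectivity: ConnectivityTable,
    structure: CrystalStructure,
) -> EnvironmentGraph:
    """Two-shell colored graph around one atom.

    Node colors (r, g, b, a): level 0 -> (0, sum of bond lengths, 0, 1);
    level 1 -> (distance to root, sum of bond lengths, 1, 1);
    level 2 -> (distance to root, 0, 2, alpha). Levels are BFS distances
    from the root, truncated at 2.
    """
    structure.atom(root_label)  # existence check
    level = {root_label: 0}
    frontier = [root_label]
    for depth in (1, 2):
        nxt = []
        for lab in frontier:
            for nb in connectivity.neighbors_of(lab):
                if nb not in level:
                    level[nb] = depth
                    nxt.append(nb)
        frontier = nxt

    g = nx.Graph(root=root_label)
    cell = structure.cell
    root_xyz = structure.atom(root_label).xyz
    for lab, lvl in level.items():
        dist = 0.0 if lvl == 0 else cell.min_image_distance(root_xyz, structure.atom(lab).xyz)
        if lvl < 2:
            color = (dist, connectivity.bond_length_sum(lab), float(lvl), 1.0)
        else:
            color = (dist, 0.0, 2.0, _level2_alpha())
        g.add_node(lab, level=lvl, color=color)
    for key in connectivity.bonds:
        a, b = tuple(key)
        if a in level and b in level:
            g.add_edge(a, b)
    return g


def _quantized_color(color, quantization: float) -> tuple:
    r, gr, b, a = color
    q = quantization
    return (round(r / q), round(gr / q), int(round(b)), int(round(a * 100)))


def graph_hash(graph: EnvironmentGraph, quantization: float = 0.01) -> str:
    """Canonical digest of the quantized colored graph.

    Iterative neighborhood color refinement (Weisfeiler-Lehman style) with a
    deterministic serialization, so the digest depends only on the
    isomorphism class of the quantized graph.
    """
    labels = {
        n: repr(_quantized_color(graph.nodes[n]["color"], quantization))
        for n in graph.nodes
    }
    n_rounds = max(2, len(graph))
    for _ in range(min(n_rounds, 6)):
        new = {}
        for n in graph.nodes:
            neigh = sorted(labels[m] for m in graph.neighbors(n))
            new[n] = hashlib.sha256(
                (labels[n] + "|" + ",".join(neigh)).encode()
            ).hexdigest()
        labels = new
    node_part = ",".join(sorted(labels.values()))
    edge_part = ",".join(
        sorted("-".join(sorted((labels[a], labels[b]))) for a, b in graph.edges)
    )
    return hashlib.sha256((node_part + "#" + edge_part).encode()).hexdigest()[:16]


def serialize_graph(graph: EnvironmentGraph) -> str:
    """One-line JSON serialization with stable integer node ids."""
    order = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(order)}
    payload = {
        "nodes": [
            {"level": graph.nodes[n]["level"], "color": list(graph.nodes[n]["color"])}
            for n in order
        ],
        "edges": sorted(sorted((idx[a], idx[b])) for a, b in graph.edges),
    }
    return json.dumps(payload, separators=(",", ":"))


def deserialize_graph(text: str) -> EnvironmentGraph:
    payload = json.loads(text)
    g = nx.Graph()
    for i, node in enumerate(payload["nodes"]):
        g.add_node(i, level=node["level"], color=tuple(node["color"]))
    for a, b in payload["edges"]:
        g.add_edge(a, b)
    return g


def graph_similarity(
    g1: EnvironmentGraph, g2: EnvironmentGraph, quantization: float = 0.01
) -> float:
    """Fraction of matching quantized color components under a level-by-level
    optimal node assignment (1.0 for identical quantized graphs)."""
    from scipy.optimize import linear_sum_assignment

    score = 0.0
    weight = 0.0
    for lvl in (0, 1, 2):
        c1 = [
            _quantized_color(g1.nodes[n]["color"], quantization)
            for n in g1.nodes
            if g1.nodes[n]["level"] == lvl
        ]
        c2 = [
            _quantized_color(g2.nodes[n]["color"], quantization)
            for n in g2.nodes
            if g2.nodes[n]["level"] == lvl
        ]
        n_max = max(len(c1), len(c2))
        if n_max == 0:
            continue
        matches = 0.0
        if c1 and c2:
            gain = np.zeros((len(c1), len(c2)))
            for i, a in enumerate(c1):
                for j, b in enumerate(c2):
                    gain[i, j] = sum(x == y for x, y in zip(a, b)) / 4.0
            rows, cols = linear_sum_assignment(-gain)
            matches = float(gain[rows, cols].sum())
        w = {0: 3.0, 1: 2.0, 2: 1.0}[lvl]
        score += w * matches / n_max
        weight += w
    return score / weight if weight else 0.0


# ---------------------------------------------------------------------------
# archetype database


@dataclass(frozen=True)
class BedeTemplate:
    """Bond-card template instantiated per bonded neighbor of one element."""

    partner_element: str
    r: float
    A: float
    B1: float
    B2: float


@dataclass(frozen=True)
class LoneTemplate:
    m: int
    A: float
    B1: float
    B2: float
    r: float
    angle: Optional[float] = None


@dataclass
class ArchetypeRecord:
    invariom_name: str
    root_element: str
    serialized_graph: str
    inner_hash: str
    parameters: list = field(default_factory=list)

    def verify_hash(self, quantization: float = 0.01) -> bool:
        return graph_hash(deserialize_graph(self.serialized_graph), quantization) == self.inner_hash

    @classmethod
    def from_graph(cls, name, root_element, graph, parameters, quantization=0.01):
        return cls(
            invariom_name=name,
            root_element=root_element,
            serialized_graph=serialize_graph(graph),
            inner_hash=graph_hash(graph, quantization),
            parameters=list(parameters),
        )


def write_database(records: Sequence[ArchetypeRecord]) -> str:
    lines = ["# archetype database: RECORD name element hash / GRAPH / cards / END"]
    for rec in records:
        lines.append(f"RECORD {rec.invariom_name} {rec.root_element} {rec.inner_hash}")
        lines.append(f"GRAPH {rec.serialized_graph}")
        for t in rec.parameters:
            if isinstance(t, BedeTemplate):
                lines.append(
                    f"BEDE {t.partner_element} {t.r:.6g} {t.A:.6g} {t.B1:.6g} {t.B2:.6g}"
                )
            else:
                card = f"LONE {t.m} {t.A:.6g} {t.B1:.6g} {t.B2:.6g} {t.r:.6g}"
                if t.angle is not None:
                    card += f" {t.angle:.6g}"
                lines.append(card)
        lines.append("END")
    return "\n".join(lines) + "\n"


def read_database(text: str) -> list[ArchetypeRecord]:
    records: list[ArchetypeRecord] = []
    current: Optional[ArchetypeRecord] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        key = tokens[0].upper()
        if key == "RECORD":
            if len(tokens) != 4:
                raise ModelError(f"database line {lineno}: RECORD needs name, element, hash")
            current = ArchetypeRecord(tokens[1], tokens[2], "", tokens[3])
        elif current is None:
            raise ModelError(f"database line {lineno}: {key} outside a RECORD block")
        elif key == "GRAPH":
            current.serialized_graph = line.split(None, 1)[1]
        elif key == "BEDE":
            el, r, a, b1, b2 = tokens[1], *map(float, tokens[2:6])
            current.parameters.append(BedeTemplate(el, r, a, b1, b2))
        elif key == "LONE":
            m = int(tokens[1])
            a, b1, b2, r = map(float, tokens[2:6])
            angle = float(tokens[6]) if len(tokens) > 6 else None
            current.parameters.append(LoneTemplate(m, a, b1, b2, r, angle))
        elif key == "END":
            records.append(current)
            current = None
        else:
            raise ModelError(f"database line {lineno}: unknown keyword {key}")
    if current is not None:
        raise ModelError("database ended inside a RECORD block")
    return records


# ---------------------------------------------------------------------------
# assignment


def _instantiate(record, atom_label, structure, connectivity) -> list[Instruction]:
    out: list[Instruction] = []
    for t in record.parameters:
        if isinstance(t, BedeTemplate):
            for nb in connectivity.neighbors_of(atom_label):
                if structure.atom(nb).element.capitalize() == t.partner_element.capitalize():
                    out.append(
                        BedeInstruction(atom_label, nb, t.r, t.A, t.B1, t.B2)
                    )
        else:
            out.append(
                LoneInstruction(t.m, atom_label, t.A, t.B1, t.B2, t.r, t.angle)
            )
    return out


def assign(
    structure: CrystalStructure,
    database: Sequence[ArchetypeRecord],
    connectivity: Optional[ConnectivityTable] = None,
    quantization: float = 0.01,
    min_fallback_score: float = 0.25,
) -> tuple[list[Instruction], dict]:
    """Assign database instruction templates to every atom.

    Exact inner-hash matches take the record's templates directly; misses
    fall back to the most similar record of the same element (flagged);
    elements with no record at all stay spherical-atom-only (flagged) —
    mixing aspherical and conventional scattering is allowed.
    """
    if not database:
        raise ModelError("archetype database is empty")
    if connectivity is None:
        connectivity = build_connectivity(structure)
    by_hash = {rec.inner_hash: rec for rec in database}
    by_element: dict[str, list[ArchetypeRecord]] = {}
    for rec in database:
        by_element.setdefault(rec.root_element.capitalize(), []).append(rec)

    instructions: list[Instruction] = []
    report: dict = {"atoms": {}, "n_exact": 0, "n_fallback": 0, "n_iam_only": 0}
    for atom in structure.atoms:
        graph = build_environment_graph(atom.label, connectivity, structure)
        digest = graph_hash(graph, quantization)
        element = atom.element.capitalize()
        entry: dict = {"element": element, "hash": digest}
        rec = by_hash.get(digest)
        if rec is not None and rec.root_element.capitalize() == element:
            entry.update(status="exact", record=rec.invariom_name, score=1.0)
            instructions.extend(_instantiate(rec, atom.label, structure, connectivity))
            report["n_exact"] += 1
        else:
            candidates = by_element.get(element, [])
            best, best_score = None, -1.0
            for cand in candidates:
                score = graph_similarity(
                    graph, deserialize_graph(cand.serialized_graph), quantization
                )
                if score > best_score:
                    best, best_score = cand, score
            if best is not None and best_score >= min_fallback_score:
                entry.update(status="fallback", record=best.invariom_name, score=best_score)
                instructions.extend(_instantiate(best, atom.label, structure, connectivity))
                report["n_fallback"] += 1
            else:
                entry.update(status="iam_only", record=None, score=0.0)
                report["n_iam_only"] += 1
        report["atoms"][atom.label] = entry
    return instructions, report
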