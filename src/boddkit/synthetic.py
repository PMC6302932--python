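"""Synthetic fixtures, simulated reflection data and the grid-density oracle.

Everything here is generated programmatically and deterministically from
(name, seed): small P1 structures with chemically sensible geometry, truth
instruction sets, simulated intensities, and a brute-force real-space
density/FFT oracle used to validate the analytic structure-factor path.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .geometry_typing import (
    ArchetypeRecord,
    BedeTemplate,
    LoneTemplate,
    build_connectivity,
    build_environment_graph,
    expand_instructions,
    graph_hash,
)
from .metrics_maps import DensityGrid
from .model import (
    AtomSite,
    BedeInstruction,
    Cell,
    CrystalStructure,
    Instruction,
    LoneInstruction,
    ModelError,
    ReflectionSet,
    RefinementConfig,
)
from .data import form_factor_coefficients

__all__ = [
    "Fixture",
    "FIXTURE_NAMES",
    "make_fixture",
    "simulate_reflections",
    "grid_density_oracle",
    "numerical_structure_factors",
    "archetype_database",
]

FIXTURE_NAMES = (
    "ethane_p1",
    "carbonyl_p1",
    "water_p1",
    "methylamine_p1",
    "mixed_metal_p1",
)

_METALS = frozenset({"Zn", "Fe"})


@dataclass
class Fixture:
    name: str
    seed: int
    structure: CrystalStructure
    instructions: list[Instruction]
    config: RefinementConfig
    noise_floor: float = 0.01


def _structure(cell: Cell, entries, jitter_rng=None, title="") -> CrystalStructure:
    """entries: (label, element, cart_xyz, u_iso|u_aniso6, riding_parent)."""
    elements = []
    atoms = []
    for label, element, cart, adp, parent in entries:
        cart = np.asarray(cart, dtype=float)
        if jitter_rng is not None:
            cart = cart + jitter_rng.normal(0.0, 0.002, size=3)
        frac = cell.cart_to_frac(cart)
        if np.ndim(adp) == 0:
            kw = {"u_iso": float(adp)}
        else:
            kw = {"u_aniso": np.asarray(adp, dtype=float)}
        atoms.append(
            AtomSite(label=label, element=element, xyz=frac, riding_parent=parent, **kw)
        )
        if element not in elements:
            elements.append(element)
    sfac = {el: form_factor_coefficients(el) for el in elements}
    return CrystalStructure(cell=cell, atoms=atoms, sfac_table=sfac, title=title)


def _tetra_dirs(axis_sign: float, azimuth0_deg: float) -> list[np.ndarray]:
    """Three unit vectors at the tetrahedral angle from the +z axis."""
    theta = math.radians(180.0 - math.degrees(math.acos(-1.0 / 3.0)))
    out = []
    for k in range(3):
        phi = math.radians(azimuth0_deg + 120.0 * k)
        out.append(
            np.array(
                [
                    math.sin(theta) * math.cos(phi),
                    math.sin(theta) * math.sin(phi),
                    axis_sign * math.cos(theta),
                ]
            )
        )
    return out


def _ethane(rng) -> tuple[CrystalStructure, list[Instruction]]:
    cell = Cell(7.0, 7.5, 8.0)
    center = np.array([3.5, 3.75, 4.0])
    cc = 1.54
    ch = 1.09
    c1 = center + [0.0, 0.0, cc / 2]
    c2 = center - [0.0, 0.0, cc / 2]
    entries = [
        ("C1", "C", c1, 0.030, None),
        ("C2", "C", c2, 0.030, None),
    ]
    for i, d in enumerate(_tetra_dirs(+1.0, 0.0), start=1):
        entries.append((f"H{i}", "H", c1 + ch * d, 0.050, "C1"))
    for i, d in enumerate(_tetra_dirs(-1.0, 60.0), start=4):
        entries.append((f"H{i}", "H", c2 + ch * d, 0.050, "C2"))
    structure = _structure(cell, entries, rng, title="ethane_p1")
    instructions: list[Instruction] = [
        BedeInstruction("C1", "C2", 0.52, 0.22, 1.1, 0.85),
        BedeInstruction("C2", "C1", 0.52, 0.22, 1.1, 0.85),
    ]
    for h in ("H1", "H2", "H3"):
        instructions.append(BedeInstruction("C1", h, 0.50, 0.12, 1.2, 0.9))
    for h in ("H4", "H5", "H6"):
        instructions.append(BedeInstruction("C2", h, 0.50, 0.12, 1.2, 0.9))
    return structure, instructions


def _carbonyl(rng) -> tuple[CrystalStructure, list[Instruction]]:
    cell = Cell(7.0, 8.0, 7.5)
    center = np.array([3.0, 4.0, 3.75])
    co = 1.21
    ch = 1.09
    c = center
    o = c + [co, 0.0, 0.0]
    h1 = c + ch * np.array([math.cos(math.radians(120)), math.sin(math.radians(120)), 0])
    h2 = c + ch * np.array([math.cos(math.radians(-120)), math.sin(math.radians(-120)), 0])
    entries = [
        ("C1", "C", c, 0.028, None),
        ("O1", "O", o, 0.032, None),
        ("H1", "H", h1, 0.048, "C1"),
        ("H2", "H", h2, 0.048, "C1"),
    ]
    structure = _structure(cell, entries, rng, title="carbonyl_p1")
    instructions: list[Instruction] = [
        BedeInstruction("C1", "O1", 0.50, 0.28, 1.0, 0.8),
        BedeInstruction("O1", "C1", 0.45, 0.20, 1.0, 0.8),
        BedeInstruction("C1", "H1", 0.50, 0.12, 1.2, 0.9),
        BedeInstruction("C1", "H2", 0.50, 0.12, 1.2, 0.9),
        LoneInstruction(9, "O1", 0.16, 1.0, 0.9, 0.35, 120.0),
        LoneInstruction(7, "O1", 0.10, 1.2, 0.9, 0.32, 180.0),
    ]
    return structure, instructions


def _water(rng) -> tuple[CrystalStructure, list[Instruction]]:
    cell = Cell(6.5, 7.0, 6.0)
    o = np.array([3.25, 3.5, 3.0])
    oh = 0.96
    half = math.radians(104.5) / 2.0
    h1 = o + oh * np.array([math.sin(half), math.cos(half), 0.0])
    h2 = o + oh * np.array([-math.sin(half), math.cos(half), 0.0])
    entries = [
        ("O1", "O", o, 0.030, None),
        ("H1", "H", h1, 0.045, "O1"),
        ("H2", "H", h2, 0.045, "O1"),
    ]
    structure = _structure(cell, entries, rng, title="water_p1")
    instructions: list[Instruction] = [
        BedeInstruction("O1", "H1", 0.45, 0.14, 1.1, 0.9),
        BedeInstruction("O1", "H2", 0.45, 0.14, 1.1, 0.9),
        LoneInstruction(2, "O1", 0.18, 1.0, 0.9, 0.35, 109.5),
    ]
    return structure, instructions


def _methylamine(rng) -> tuple[CrystalStructure, list[Instruction]]:
    cell = Cell(8.0, 8.5, 9.0)
    center = np.array([4.0, 4.25, 4.5])
    cn = 1.47
    ch = 1.09
    nh = 1.01
    c = center - [0.0, 0.0, cn / 2]
    n = center + [0.0, 0.0, cn / 2]
    entries = [
        ("C1", "C", c, 0.030, None),
        ("N1", "N", n, (0.030, 0.025, 0.028, 0.002, 0.001, 0.003), None),
    ]
    for i, d in enumerate(_tetra_dirs(-1.0, 0.0), start=1):
        entries.append((f"H{i}", "H", c + ch * d, 0.050, "C1"))
    # two amine H's, staggered relative to the methyl
    for i, d in enumerate(_tetra_dirs(+1.0, 60.0)[:2], start=4):
        entries.append((f"H{i}", "H", n + nh * d, 0.050, "N1"))
    structure = _structure(cell, entries, rng, title="methylamine_p1")
    instructions: list[Instruction] = [
        BedeInstruction("C1", "N1", 0.55, 0.20, 1.0, 0.85),
        BedeInstruction("N1", "C1", 0.50, 0.18, 1.0, 0.85),
        BedeInstruction("C1", "H1", 0.50, 0.12, 1.2, 0.9),
        BedeInstruction("C1", "H2", 0.50, 0.12, 1.2, 0.9),
        BedeInstruction("C1", "H3", 0.50, 0.12, 1.2, 0.9),
        BedeInstruction("N1", "H4", 0.48, 0.13, 1.1, 0.9),
        BedeInstruction("N1", "H5", 0.48, 0.13, 1.1, 0.9),
        LoneInstruction(1, "N1", 0.20, 1.0, 0.9, 0.38),
    ]
    return structure, instructions


def _mixed_metal(rng) -> tuple[CrystalStructure, list[Instruction]]:
    cell = Cell(8.0, 8.5, 9.0)
    zn = np.array([4.0, 4.25, 4.5])
    o = zn + [2.05, 0.0, 0.0]
    cl = zn + [0.0, 0.0, 2.25]
    oh = 0.96
    half = math.radians(107.0) / 2.0
    h1 = o + oh * np.array([math.cos(half), math.sin(half), 0.0])
    h2 = o + oh * np.array([math.cos(half), -math.sin(half), 0.0])
    entries = [
        ("Zn1", "Zn", zn, 0.022, None),
        ("Cl1", "Cl", cl, 0.030, None),
        ("O1", "O", o, 0.032, None),
        ("H1", "H", h1, 0.048, "O1"),
        ("H2", "H", h2, 0.048, "O1"),
    ]
    structure = _structure(cell, entries, rng, title="mixed_metal_p1")
    # O is three-coordinate here (Zn, H1, H2) -> single-lobe code
    instructions: list[Instruction] = [
        BedeInstruction("O1", "H1", 0.45, 0.14, 1.1, 0.9),
        BedeInstruction("O1", "H2", 0.45, 0.14, 1.1, 0.9),
        LoneInstruction(1, "O1", 0.18, 1.0, 0.9, 0.35),
    ]
    return structure, instructions


_BUILDERS = {
    "ethane_p1": _ethane,
    "carbonyl_p1": _carbonyl,
    "water_p1": _water,
    "methylamine_p1": _methylamine,
    "mixed_metal_p1": _mixed_metal,
}


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Build a named fixture; bit-identical for identical (name, seed)."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ModelError(
            f"unknown fixture {name!r}; catalog: {', '.join(FIXTURE_NAMES)}"
        ) from None
    rng = np.random.default_rng([seed, zlib.crc32(name.encode())])
    structure, instructions = builder(rng)
    config = RefinementConfig(elongation=1.0)
    return Fixture(name=name, seed=seed, structure=structure,
                   instructions=instructions, config=config)


# ---------------------------------------------------------------------------
# simulated data


def unique_hkl(cell: Cell, d_min: float) -> np.ndarray:
    """All Friedel-unique lattice points with d >= d_min (excluding 000)."""
    limits = [int(math.ceil(length / d_min)) + 1 for length in cell.lengths]
    grids = np.meshgrid(*[np.arange(-n, n + 1) for n in limits], indexing="ij")
    hkl = np.stack([g.ravel() for g in grids], axis=1)
    s = cell.s_values(hkl)
    keep = (s > 1e-9) & (2.0 * s <= 1.0 / d_min + 1e-9)
    hkl = hkl[keep]
    h, k, l = hkl.T
    half = (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))
    hkl = hkl[half]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def simulate_reflections(
    fixture: Fixture,
    d_min: float = 0.8,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> ReflectionSet:
    """Simulate Fo^2 from the fixture's truth model.

    Fo^2 = |F_truth|^2 (truth osf included) perturbed by multiplicative
    Gaussian noise of the stated fraction; sigmas follow the noise model
    with a floor.
    """
    if d_min <= 0:
        raise ModelError("d_min must be positive")
    if d_min < 0.3:
        raise ModelError("d_min finer than 0.3 A exceeds the toy-size guard")
    from .scattering import structure_factor

    structure = fixture.structure
    hkl = unique_hkl(structure.cell, d_min)
    connectivity = build_connectivity(structure)
    placed = expand_instructions(fixture.instructions, structure, connectivity)
    f = structure_factor(structure, placed, fixture.config, hkl)
    fo2_true = np.abs(f) ** 2

    rng = np.random.default_rng([seed, 0x5EED])
    nf_eff = noise_fraction if noise_fraction > 0 else fixture.noise_floor
    floor = 1e-4 * float(np.max(fo2_true))
    sigma = np.maximum(nf_eff * fo2_true, floor)
    fo2 = fo2_true.copy()
    if noise_fraction > 0:
        fo2 = fo2_true + sigma * rng.standard_normal(len(fo2_true))
    refl = ReflectionSet(hkl, fo2, sigma)
    refl.attach_cell(structure.cell)
    return refl


# ---------------------------------------------------------------------------
# grid oracle


def grid_density_oracle(
    structure: CrystalStructure,
    instructions,
    spacing: float = 0.1,
    config: RefinementConfig | None = None,
) -> DensityGrid:
    """Real-space model density sampled on a grid (P1 only).

    Each form-factor Gaussian term (and the constant c) is convolved with
    the atom's Debye-Waller smearing analytically; deformation lobes are
    added with their displacement-coupled spreads. FFT of this grid is the
    numerical structure-factor oracle for the analytic path.
    """
    if len(structure.symmetry_ops) != 1:
        raise ModelError("grid oracle handles P1 structures only")
    if spacing > 0.15:
        raise ModelError("oracle grid spacing must be <= 0.15 A")
    cfg = config or RefinementConfig()
    cell = structure.cell
    shape = tuple(
        max(4, int(math.ceil(length / spacing)) + int(math.ceil(length / spacing)) % 2)
        for length in cell.lengths
    )
    fx = np.arange(shape[0]) / shape[0]
    fy = np.arange(shape[1]) / shape[1]
    fz = np.arange(shape[2]) / shape[2]
    grid_frac = np.stack(np.meshgrid(fx, fy, fz, indexing="ij"), axis=-1)
    metric = cell.metric
    m_orth = cell.orthogonalization
    rho = np.zeros(shape)

    def add_iso_gaussian(center_frac, amplitude, p):
        # reciprocal f = amplitude * exp(-p s^2)  ->  real-space Gaussian
        d = grid_frac - center_frac
        d -= np.round(d)
        r2 = np.einsum("...i,ij,...j->...", d, metric, d)
        nonlocal rho
        rho = rho + amplitude * (4.0 * math.pi / p) ** 1.5 * np.exp(
            -4.0 * math.pi**2 * r2 / p
        )

    def add_aniso_gaussian(center_frac, amplitude, b_term, ustar):
        # f = amplitude * exp(-b s^2 - 2 pi^2 h.U*.h); quadratic form in q_cart
        u_cart = m_orth.T @ ustar @ m_orth
        a_mat = (b_term / 4.0) * np.eye(3) + 2.0 * math.pi**2 * u_cart
        a_inv = np.linalg.inv(a_mat)
        det = np.linalg.det(a_mat)
        d = grid_frac - center_frac
        d -= np.round(d)
        d_cart = d @ m_orth.T
        q = np.einsum("...i,ij,...j->...", d_cart, a_inv, d_cart)
        nonlocal rho
        rho = rho + amplitude * math.pi**1.5 / math.sqrt(det) * np.exp(
            -math.pi**2 * q
        )

    eight_pi_sq = 8.0 * math.pi**2
    for atom in structure.atoms:
        coeffs = structure.sfac_table[atom.element]
        terms = list(zip(coeffs.a, coeffs.b)) + [(coeffs.c, 0.0)]
        if atom.u_aniso is None:
            for a_i, b_i in terms:
                if a_i == 0.0:
                    continue
                add_iso_gaussian(
                    atom.xyz, atom.occupancy * a_i, b_i + eight_pi_sq * atom.u_iso
                )
        else:
            ustar = atom.u_star_matrix(cell)
            for a_i, b_i in terms:
                if a_i == 0.0:
                    continue
                add_aniso_gaussian(atom.xyz, atom.occupancy * a_i, b_i, ustar)

    if instructions and cfg.k_A != 0.0:
        from .scattering import lobe_exponent

        connectivity = build_connectivity(structure)
        placed = expand_instructions(instructions, structure, connectivity)
        u_eq = {a.label: a.u_eq(cell) for a in structure.atoms}
        for g in placed:
            k_b = cfg.k_B1 if g.amplitude >= 0 else cfg.k_B2
            p = lobe_exponent(
                g.spread, u_eq[g.host_atom], k_B=k_b,
                additive=cfg.additive_spread_coupling,
            )
            add_iso_gaussian(g.center_frac, cfg.k_A * g.amplitude, p)

    return DensityGrid(values=rho, cell=cell)


def numerical_structure_factors(
    grid: DensityGrid, hkl, osf: float = 1.0
) -> np.ndarray:
    """F(h) by FFT of the sampled density: F(h) = (V/N) sum rho e^{2 pi i h.x}."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    ft = np.fft.fftn(grid.values)
    shape = grid.values.shape
    n_tot = np.prod(shape)
    out = np.empty(len(hkl), dtype=complex)
    for i, (h, k, l) in enumerate(hkl):
        out[i] = np.conj(ft[h % shape[0], k % shape[1], l % shape[2]])
    return osf * out * grid.cell.volume / n_tot


# ---------------------------------------------------------------------------
# archetype database generation from a fixture's truth instructions


def archetype_database(fixture: Fixture, quantization: float = 0.01) -> list[ArchetypeRecord]:
    """Build archetype records from a fixture's own atoms and truth cards.

    Every non-metal atom gets a record keyed by its environment-graph hash
    (possibly with an empty template list); metal atoms are deliberately
    absent so assignment falls back to spherical-atom scattering for them.
    """
    structure = fixture.structure
    connectivity = build_connectivity(structure)
    by_root: dict[str, list] = {a.label: [] for a in structure.atoms}
    for instr in fixture.instructions:
        if isinstance(instr, BedeInstruction):
            partner = structure.atom(instr.atom2).element
            by_root[instr.atom1].append(
                BedeTemplate(partner, instr.r, instr.A, instr.B1, instr.B2)
            )
        else:
            by_root[instr.atom].append(
                LoneTemplate(instr.m, instr.A, instr.B1, instr.B2, instr.r, instr.angle)
            )
    records: dict[str, ArchetypeRecord] = {}
    for atom in structure.atoms:
        if atom.element in _METALS:
            continue
        graph = build_environment_graph(atom.label, connectivity, structure)
        digest = graph_hash(graph, quantization)
        if digest in records:
            continue
        templates = list(dict.fromkeys(by_root[atom.label]))
        records[digest] = ArchetypeRecord.from_graph(
            f"{atom.element}.{digest[:6]}.{fixture.name}",
            atom.element,
            graph,
            templates,
            quantization,
        )
    return list(records.values())
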