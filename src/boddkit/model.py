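"""Core domain types shared across the toolkit.

Conventions: fractional coordinates, cell lengths in angstrom, cell angles
in degrees, displacement parameters in angstrom^2 following the SHELX
U_ij convention (exponent ``-2 pi^2 sum U_ij h_i h_j a*_i a*_j``), and
``s = sin(theta)/lambda`` in inverse angstrom.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "Cell",
    "SymmetryOp",
    "GaussianCoefficients",
    "AtomSite",
    "CrystalStructure",
    "ReflectionSet",
    "BedeInstruction",
    "LoneInstruction",
    "Instruction",
    "RefinementConfig",
    "PlacedGaussian",
]


class ModelError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class Cell:
    """Unit-cell metric: lengths in angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ModelError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ModelError(f"cell angles must lie in (0, 180): {self}")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @property
    def orthogonalization(self) -> np.ndarray:
        """3x3 matrix M with x_cart = M @ x_frac (PDB convention)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in self.angles)
        sg = math.sin(math.radians(self.gamma))
        v = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v <= 0:
            raise ModelError(f"singular cell metric: {self}")
        v = math.sqrt(v)
        a, b, c = self.lengths
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * v / sg],
            ]
        )

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.orthogonalization)))

    @property
    def metric(self) -> np.ndarray:
        """Real-space metric tensor G (G_ij = a_i . a_j)."""
        m = self.orthogonalization
        return m.T @ m

    @property
    def reciprocal_metric(self) -> np.ndarray:
        return np.linalg.inv(self.metric)

    @property
    def reciprocal_lengths(self) -> np.ndarray:
        """|a*|, |b*|, |c*| in 1/angstrom."""
        return np.sqrt(np.diag(self.reciprocal_metric))

    def frac_to_cart(self, xyz: Sequence[float]) -> np.ndarray:
        return self.orthogonalization @ np.asarray(xyz, dtype=float)

    def cart_to_frac(self, xyz: Sequence[float]) -> np.ndarray:
        return np.linalg.solve(self.orthogonalization, np.asarray(xyz, dtype=float))

    def distance(self, frac_a: Sequence[float], frac_b: Sequence[float]) -> float:
        """Direct (non-periodic) distance between two fractional positions."""
        d = np.asarray(frac_b, dtype=float) - np.asarray(frac_a, dtype=float)
        return float(np.sqrt(d @ self.metric @ d))

    def min_image_distance(self, frac_a, frac_b) -> float:
        """Distance to the nearest periodic image."""
        d = np.asarray(frac_b, dtype=float) - np.asarray(frac_a, dtype=float)
        d -= np.round(d)
        return float(np.sqrt(d @ self.metric @ d))

    def s_values(self, hkl: np.ndarray) -> np.ndarray:
        """sin(theta)/lambda = 1/(2 d) for each reflection."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = np.einsum("ni,ij,nj->n", hkl, self.reciprocal_metric, hkl)
        return 0.5 * np.sqrt(np.maximum(inv_d2, 0.0))


@dataclass(frozen=True)
class SymmetryOp:
    """Affine map on fractional coordinates: x -> R @ x + t."""

    rotation: tuple = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
    translation: tuple = (0.0, 0.0, 0.0)

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    def apply(self, xyz: Sequence[float]) -> np.ndarray:
        return self.R @ np.asarray(xyz, dtype=float) + self.t

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.R, np.eye(3)) and np.allclose(self.t, 0.0)

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls()


@dataclass(frozen=True)
class GaussianCoefficients:
    """Four-Gaussian-plus-constant analytic form factor coefficients.

    f(s) = sum_i a_i exp(-b_i s^2) + c, with s = sin(theta)/lambda.
    """

    a: tuple[float, float, float, float]
    b: tuple[float, float, float, float]
    c: float = 0.0

    def __post_init__(self) -> None:
        if len(self.a) != 4 or len(self.b) != 4:
            raise ModelError("expected exactly four Gaussian terms")
        if any(bi < 0 for bi in self.b):
            raise ModelError("Gaussian exponents must be non-negative")

    @property
    def electron_count(self) -> float:
        """f(0) = sum(a) + c, approximately the element's Z."""
        return float(sum(self.a) + self.c)

    def validate_against_z(self, z: int, rtol: float = 0.02) -> None:
        if abs(self.electron_count - z) > rtol * max(z, 1):
            raise ModelError(
                f"f(0)={self.electron_count:.3f} deviates from Z={z} by more than {rtol:.0%}"
            )


@dataclass
class AtomSite:
    """One atom of the asymmetric unit."""

    label: str
    element: str
    xyz: np.ndarray  # fractional
    occupancy: float = 1.0
    u_iso: Optional[float] = None  # angstrom^2
    u_aniso: Optional[np.ndarray] = None  # (U11,U22,U33,U23,U13,U12)
    riding_parent: Optional[str] = None
    ideal_xh: Optional[float] = None  # recorded ideal X-H distance, angstrom

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float)
        if not 0.0 < self.occupancy <= 1.0 + 1e-9:
            raise ModelError(f"atom {self.label}: occupancy {self.occupancy} outside (0, 1]")
        if self.u_iso is None and self.u_aniso is None:
            raise ModelError(f"atom {self.label}: no displacement parameters")
        if self.u_iso is not None and self.u_iso <= 0:
            raise ModelError(f"atom {self.label}: U_iso must be positive")

    @property
    def is_anisotropic(self) -> bool:
        return self.u_aniso is not None

    def u_star_matrix(self, cell: Cell) -> np.ndarray:
        """Symmetric 3x3 matrix N U N with N = diag(a*, b*, c*)."""
        u11, u22, u33, u23, u13, u12 = self.u_aniso
        u = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
        n = np.diag(cell.reciprocal_lengths)
        return n @ u @ n

    def u_eq(self, cell: Cell) -> float:
        """Isotropic-equivalent displacement: tr(G . N U N) / 3."""
        if self.u_aniso is None:
            return float(self.u_iso)
        return float(np.trace(cell.metric @ self.u_star_matrix(cell)) / 3.0)

    def validate_adp(self, cell: Cell) -> None:
        if self.u_aniso is not None:
            eig = np.linalg.eigvalsh(self.u_star_matrix(cell))
            if eig.min() <= 0:
                raise ModelError(
                    f"atom {self.label}: U_ij not positive definite (eigenvalues {eig})"
                )

    def copy(self) -> "AtomSite":
        return AtomSite(
            label=self.label,
            element=self.element,
            xyz=self.xyz.copy(),
            occupancy=self.occupancy,
            u_iso=self.u_iso,
            u_aniso=None if self.u_aniso is None else self.u_aniso.copy(),
            riding_parent=self.riding_parent,
            ideal_xh=self.ideal_xh,
        )


@dataclass
class CrystalStructure:
    cell: Cell
    atoms: list[AtomSite]
    sfac_table: dict[str, GaussianCoefficients]
    symmetry_ops: list[SymmetryOp] = field(default_factory=lambda: [SymmetryOp.identity()])
    wavelength: float = 0.71073
    title: str = ""
    extra_cards: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(op.is_identity for op in self.symmetry_ops):
            raise ModelError("identity operation missing from symmetry_ops")
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ModelError(f"duplicate atom labels: {dupes}")
        for atom in self.atoms:
            if atom.element not in self.sfac_table:
                raise ModelError(
                    f"atom {atom.label}: element {atom.element!r} has no scattering "
                    f"coefficients (SFAC lists {sorted(self.sfac_table)})"
                )

    def atom(self, label: str) -> AtomSite:
        for a in self.atoms:
            if a.label == label:
                return a
        raise KeyError(f"no atom labelled {label!r}")

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            cell=self.cell,
            atoms=[a.copy() for a in self.atoms],
            sfac_table=dict(self.sfac_table),
            symmetry_ops=list(self.symmetry_ops),
            wavelength=self.wavelength,
            title=self.title,
            extra_cards=list(self.extra_cards),
        )


@dataclass
class ReflectionSet:
    """Merged unique reflections with Fo^2, sigma and resolution."""

    hkl: np.ndarray  # (n, 3) int
    fo2: np.ndarray
    sigma: np.ndarray
    s: Optional[np.ndarray] = None  # sin(theta)/lambda, set on cell attachment

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.fo2 = np.asarray(self.fo2, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len({tuple(h) for h in self.hkl}) != len(self.hkl):
            raise ModelError("duplicate hkl entries after merging")
        if np.any(self.sigma <= 0):
            raise ModelError("sigma values must be positive")

    def __len__(self) -> int:
        return len(self.hkl)

    def attach_cell(self, cell: Cell) -> "ReflectionSet":
        self.s = cell.s_values(self.hkl)
        return self

    def subset(self, mask: np.ndarray) -> "ReflectionSet":
        r = ReflectionSet(self.hkl[mask], self.fo2[mask], self.sigma[mask])
        if self.s is not None:
            r.s = self.s[mask]
        return r


@dataclass(frozen=True)
class BedeInstruction:
    """Bond-density card: +A lobe on the bond, -A lobe at atom1.

    Card syntax: ``BEDE atom1 atom2 r A B1 B2``. r is the distance of the
    positive lobe from atom1 along the bond to atom2; B1/B2 are the spreads
    of the +A/-A lobes, both coupled to atom1's displacement parameters.
    """

    atom1: str
    atom2: str
    r: float
    A: float
    B1: float
    B2: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ModelError(f"BEDE {self.atom1} {self.atom2}: r must be positive")
        if self.B1 <= 0 or self.B2 <= 0:
            raise ModelError(f"BEDE {self.atom1} {self.atom2}: spreads must be positive")

    @property
    def n_free_parameters(self) -> int:
        """r, A, B1, B2 — amplitude negation removes one of the raw six."""
        return 4

    @property
    def n_raw_parameters(self) -> int:
        """Two lobes x (position, amplitude, spread)."""
        return 6

    def to_card(self) -> str:
        return (
            f"BEDE {self.atom1} {self.atom2} "
            f"{self.r:.6g} {self.A:.6g} {self.B1:.6g} {self.B2:.6g}"
        )


#: m-codes whose geometry takes an explicit angle argument
ANGLE_M_CODES = frozenset({2, 3, 7, 9})
#: all supported lone-pair geometry codes
VALID_M_CODES = frozenset({1, 2, 3, 6, 7, 9, 12, 15})


@dataclass(frozen=True)
class LoneInstruction:
    """Lone-pair card: ``LONE m atom A B1 B2 r [angle]``.

    m selects the geometric construction; the compensating negative lobe at
    the atom carries a multiple of A so the electron count stays balanced.
    """

    m: int
    atom: str
    A: float
    B1: float
    B2: float
    r: float
    angle: Optional[float] = None

    def __post_init__(self) -> None:
        if self.m not in VALID_M_CODES:
            raise ModelError(
                f"LONE on {self.atom}: unsupported m={self.m} "
                f"(supported: {sorted(VALID_M_CODES)})"
            )
        takes_angle = self.m in ANGLE_M_CODES
        if takes_angle and self.angle is None:
            raise ModelError(f"LONE m={self.m} on {self.atom}: angle required")
        if not takes_angle and self.angle is not None:
            raise ModelError(f"LONE m={self.m} on {self.atom}: angle not allowed")
        if self.r <= 0 or self.B1 <= 0 or self.B2 <= 0:
            raise ModelError(f"LONE on {self.atom}: r and spreads must be positive")

    def to_card(self) -> str:
        card = (
            f"LONE {self.m} {self.atom} "
            f"{self.A:.6g} {self.B1:.6g} {self.B2:.6g} {self.r:.6g}"
        )
        if self.angle is not None:
            card += f" {self.angle:.6g}"
        return card


Instruction = Union[BedeInstruction, LoneInstruction]


@dataclass
class RefinementConfig:
    """Refinement-time knobs.

    Exactly three global scale factors (k_A, k_B1, k_B2) multiply all card
    A, B1 and B2 values; individual card parameters stay fixed. The riding-H
    elongation default is 1.14 in deformation mode and 1.0 in IAM mode.
    """

    osf: float = 1.0
    k_A: float = 1.0
    k_B1: float = 1.0
    k_B2: float = 1.0
    weight_a: float = 0.0
    weight_b: float = 0.0
    elongation: float = 1.14
    max_cycles: int = 50
    convergence_tol: float = 0.01
    refine_k: bool = False
    additive_spread_coupling: bool = False  # B + 8 pi^2 U_eq instead of B * 8 pi^2 U_eq

    N_GLOBAL_ASPHERICITY_SCALES = 3

    def __post_init__(self) -> None:
        if self.osf <= 0:
            raise ModelError("overall scale factor must be positive")
        if min(self.k_A, self.k_B1, self.k_B2) < 0:
            raise ModelError("global asphericity scales must be non-negative")

    @classmethod
    def iam_mode(cls, **kw) -> "RefinementConfig":
        kw.setdefault("elongation", 1.0)
        return cls(k_A=0.0, **kw)

    def copy(self) -> "RefinementConfig":
        return dataclasses.replace(self)


@dataclass(frozen=True)
class PlacedGaussian:
    """A single expanded deformation lobe.

    amplitude is signed and already includes the lobe occupancy; spread is
    the dimensionless B multiplier coupled to the host atom's displacement.
    """

    center: tuple[float, float, float]  # fractional
    amplitude: float
    spread: float
    host_atom: str
    origin: str = ""

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ModelError(f"lobe from {self.origin!r}: spread must be positive")
        if not math.isfinite(self.amplitude):
            raise ModelError(f"lobe from {self.origin!r}: non-finite amplitude")

    @property
    def center_frac(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)
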