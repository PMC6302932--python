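"""Model-quality statistics and real-space density maps.

Covers the unweighted/weighted residuals (R1, wR2, GooF), the fold-based
cross-validated residual R_complete with its bias statistic b, ADP
comparison statistics (mean difference and population standard deviation),
and difference/deformation density grids.
"""

from __future__ import annotations

import math
import struct as _struct
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .geometry_typing import build_connectivity, expand_instructions
from .model import (
    Cell,
    CrystalStructure,
    Instruction,
    ModelError,
    ReflectionSet,
    RefinementConfig,
)
from .refine import compute_weights, refine
from .scattering import EIGHT_PI_SQ, lobe_exponent, structure_factor

__all__ = [
    "MetricsReport",
    "AdpComparison",
    "DensityGrid",
    "r_factors",
    "rcomplete",
    "bias_b",
    "BIAS_DEFINITIONS",
    "adp_stats",
    "difference_map",
    "deformation_map",
]


# ---------------------------------------------------------------------------
# residuals


def r_factors(
    fo2,
    sigma,
    fc2,
    weights=None,
    threshold: float = 2.0,
    n_params: int = 0,
) -> tuple[float, float, float]:
    """R1 (amplitudes, reflections with Fo^2 > threshold*sigma), wR2 and GooF.

    R1 = sum||Fo|-|Fc|| / sum|Fo|;
    wR2 = sqrt(sum w (Fo^2-Fc^2)^2 / sum w (Fo^2)^2).
    """
    fo2 = np.asarray(fo2, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    fc2 = np.asarray(fc2, dtype=float)
    if weights is None:
        weights = 1.0 / sigma**2
    weights = np.asarray(weights, dtype=float)
    strong = fo2 > threshold * sigma
    if strong.sum() == 0:
        raise ModelError("no reflections above the R1 intensity threshold")
    fo = np.sqrt(np.maximum(fo2[strong], 0.0))
    fc = np.sqrt(fc2[strong])
    r1 = float(np.sum(np.abs(fo - fc)) / np.sum(fo))
    wr2 = float(
        math.sqrt(
            np.sum(weights * (fo2 - fc2) ** 2) / max(np.sum(weights * fo2**2), 1e-300)
        )
    )
    dof = max(len(fo2) - n_params, 1)
    goof = float(math.sqrt(np.sum(weights * (fo2 - fc2) ** 2) / dof))
    return r1, wr2, goof


def rcomplete(
    structure: CrystalStructure,
    instructions: Sequence[Instruction],
    reflections: ReflectionSet,
    config: RefinementConfig,
    k: int = 10,
    seed: int = 0,
    shake: float = 0.005,
    threshold: float = 2.0,
) -> float:
    """Cross-validated R1 over fold-by-fold excluded reflections.

    Reflections are split into k seeded random sets; for each set the model
    is re-refined with that set excluded (after a small seeded coordinate
    shake to decorrelate it from the full-data solution) and the excluded
    reflections' amplitude residuals are evaluated with that fold's model.
    The contributions of all folds assemble the complete residual.
    """
    if k < 2:
        raise ModelError("rcomplete needs k >= 2 folds")
    n = len(reflections)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    num = 0.0
    den = 0.0
    cell = structure.cell
    for fold_idx, fold in enumerate(folds):
        if len(fold) == 0:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[fold] = True
        shaken = structure.copy()
        for atom in shaken.atoms:
            if atom.riding_parent is not None:
                continue
            dcart = rng.normal(0.0, shake, size=3)
            atom.xyz = cell.cart_to_frac(cell.frac_to_cart(atom.xyz) + dcart)
        result = refine(shaken, instructions, reflections, config, free_mask=mask)
        if not result.converged:
            warnings.warn(f"rcomplete fold {fold_idx} did not converge; excluded")
            continue
        fc2 = np.abs(result.fc[mask]) ** 2
        fo2 = reflections.fo2[mask]
        sig = reflections.sigma[mask]
        strong = fo2 > threshold * sig
        fo = np.sqrt(np.maximum(fo2[strong], 0.0))
        fc = np.sqrt(fc2[strong])
        num += float(np.sum(np.abs(fo - fc)))
        den += float(np.sum(fo))
    if den == 0.0:
        raise ModelError("rcomplete: no usable excluded reflections")
    return num / den


def _bias_gap_difference(r1_iam, r1_bodd, rc_iam, rc_bodd) -> float:
    return (rc_iam - r1_iam) - (rc_bodd - r1_bodd)


def _bias_gap_ratio(r1_iam, r1_bodd, rc_iam, rc_bodd) -> float:
    return (rc_iam / max(r1_iam, 1e-300)) - (rc_bodd / max(r1_bodd, 1e-300))


BIAS_DEFINITIONS: dict[str, Callable[..., float]] = {
    "gap_difference": _bias_gap_difference,
    "gap_ratio": _bias_gap_ratio,
}


def bias_b(
    r1_iam: float,
    r1_bodd: float,
    rc_iam: float,
    rc_bodd: float,
    definition: str = "gap_difference",
) -> float:
    """Bias statistic b comparing the cross-validation gaps of two models.

    Positive b: the deformation model shrinks the R_complete-R1 gap, i.e.
    reduces bias; negative b: it adds bias. The default definition
    (difference of gaps) is this toolkit's own choice and is swappable by
    name.
    """
    try:
        fn = BIAS_DEFINITIONS[definition]
    except KeyError:
        raise ModelError(
            f"unknown bias definition {definition!r}; choices: {sorted(BIAS_DEFINITIONS)}"
        )
    return float(fn(r1_iam, r1_bodd, rc_iam, rc_bodd))


@dataclass
class MetricsReport:
    r1_iam: float
    r1_bodd: float
    rcomplete_iam: Optional[float] = None
    rcomplete_bodd: Optional[float] = None
    bias: Optional[float] = None
    osf_iam: Optional[float] = None
    osf_bodd: Optional[float] = None

    @property
    def delta_r1(self) -> float:
        return self.r1_iam - self.r1_bodd

    def as_dict(self) -> dict:
        return {
            "r1_iam": self.r1_iam,
            "r1_bodd": self.r1_bodd,
            "delta_r1": self.delta_r1,
            "rcomplete_iam": self.rcomplete_iam,
            "rcomplete_bodd": self.rcomplete_bodd,
            "bias_b": self.bias,
            "osf_iam": self.osf_iam,
            "osf_bodd": self.osf_bodd,
        }


# ---------------------------------------------------------------------------
# ADP comparison


@dataclass
class AdpComparison:
    """Per-component ADP differences (model_a minus model_b)."""

    differences: np.ndarray
    md: float
    sd: float
    n: int
    labels: list[str] = field(default_factory=list)


def adp_stats(model_a: CrystalStructure, model_b: CrystalStructure) -> AdpComparison:
    """Mean difference MD = (1/N) sum d_i of corresponding ADP components and
    its population standard deviation (divisor N). Anisotropic atoms
    contribute six components, isotropic one; mixed pairs compare U_eq."""
    la, lb = set(model_a.labels), set(model_b.labels)
    if la != lb:
        raise ModelError(
            f"atom label mismatch: only in a {sorted(la - lb)}, only in b {sorted(lb - la)}"
        )
    diffs: list[float] = []
    labels: list[str] = []
    for label in model_a.labels:
        a = model_a.atom(label)
        b = model_b.atom(label)
        if a.u_aniso is not None and b.u_aniso is not None:
            diffs.extend((a.u_aniso - b.u_aniso).tolist())
            labels.extend([label] * 6)
        elif a.u_aniso is None and b.u_aniso is None:
            diffs.append(a.u_iso - b.u_iso)
            labels.append(label)
        else:
            diffs.append(a.u_eq(model_a.cell) - b.u_eq(model_b.cell))
            labels.append(label)
    d = np.asarray(diffs)
    md = float(d.mean())
    sd = float(np.sqrt(np.mean((d - md) ** 2)))  # population convention
    return AdpComparison(differences=d, md=md, sd=sd, n=len(d), labels=labels)


# ---------------------------------------------------------------------------
# density grids


@dataclass
class DensityGrid:
    """Real-space scalar field over the unit cell (e/A^3)."""

    values: np.ndarray  # (nx, ny, nz)
    cell: Cell

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        nx, ny, nz = self.values.shape
        return (self.cell.a / nx, self.cell.b / ny, self.cell.c / nz)

    @property
    def rho_min(self) -> float:
        return float(self.values.min())

    @property
    def rho_max(self) -> float:
        return float(self.values.max())

    def integral(self) -> float:
        """Quadrature integral over the cell in electrons."""
        return float(self.values.mean() * self.cell.volume)

    def value_at(self, frac_xyz) -> float:
        """Nearest-voxel lookup at a fractional position."""
        idx = tuple(
            int(round(x * n)) % n for x, n in zip(np.asarray(frac_xyz), self.shape)
        )
        return float(self.values[idx])

    def to_text(self) -> str:
        nx, ny, nz = self.shape
        c = self.cell
        head = (
            f"# density grid {nx} {ny} {nz}\n"
            f"# cell {c.a:.6f} {c.b:.6f} {c.c:.6f} {c.alpha:.4f} {c.beta:.4f} {c.gamma:.4f}\n"
            "# values in e/A^3, z fastest\n"
        )
        body = "\n".join(f"{v:.6e}" for v in self.values.ravel())
        return head + body + "\n"

    def write_ccp4(self, path) -> None:
        """Minimal CCP4/MRC mode-2 map file."""
        nx, ny, nz = self.shape
        c = self.cell
        header = bytearray(1024)
        _struct.pack_into("<3i", header, 0, nz, ny, nx)  # NC, NR, NS (z fastest here)
        _struct.pack_into("<i", header, 12, 2)  # MODE 2: float32
        _struct.pack_into("<3i", header, 16, 0, 0, 0)  # start
        _struct.pack_into("<3i", header, 28, nx, ny, nz)  # sampling
        _struct.pack_into("<6f", header, 40, c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        _struct.pack_into("<3i", header, 64, 3, 2, 1)  # col=z, row=y, sec=x
        _struct.pack_into(
            "<3f", header, 76, self.rho_min, self.rho_max, float(self.values.mean())
        )
        _struct.pack_into("<2i", header, 88, 1, 0)  # P1, no symmetry records
        header[208:212] = b"MAP "
        header[212:216] = bytes([0x44, 0x41, 0x00, 0x00])  # little-endian stamp
        with open(path, "wb") as fh:
            fh.write(bytes(header))
            fh.write(self.values.astype("<f4").tobytes(order="C"))


def _grid_shape(cell: Cell, spacing: float) -> tuple[int, int, int]:
    dims = []
    for length in cell.lengths:
        n = int(math.ceil(length / spacing))
        if n % 2:
            n += 1
        dims.append(max(n, 4))
    return tuple(dims)


def difference_map(
    structure: CrystalStructure,
    instructions: Sequence[Instruction],
    reflections: ReflectionSet,
    grid_spacing: float = 0.1,
    config: Optional[RefinementConfig] = None,
) -> DensityGrid:
    """Fo-Fc difference Fourier synthesis.

    Coefficients (|Fo| - |Fc|) e^{i phi_c} on the model's absolute scale
    (observed amplitudes are divided by the overall scale factor), expanded
    with Friedel mates and synthesized by FFT.
    """
    cfg = config or RefinementConfig()
    hkl = np.asarray(reflections.hkl, dtype=int)
    s = structure.cell.s_values(hkl)
    d_min = float(1.0 / (2.0 * s.max()))
    if grid_spacing > d_min / 2.0 + 1e-9:
        raise ModelError(
            f"grid spacing {grid_spacing} A aliases data to d_min {d_min:.3f} A; "
            f"need spacing <= {d_min / 2.0:.3f}"
        )
    connectivity = build_connectivity(structure)
    placed = expand_instructions(instructions, structure, connectivity) if instructions else []
    f_scaled = structure_factor(structure, placed, cfg, hkl)
    f_model = f_scaled / cfg.osf  # absolute scale
    fo = np.sqrt(np.maximum(reflections.fo2, 0.0)) / cfg.osf
    delta = (fo - np.abs(f_model)) * np.exp(1j * np.angle(f_model))

    shape = _grid_shape(structure.cell, grid_spacing)
    coef = np.zeros(shape, dtype=complex)
    for (h, k, l), df in zip(hkl, delta):
        if h == 0 and k == 0 and l == 0:
            continue
        idx = ((-h) % shape[0], (-k) % shape[1], (-l) % shape[2])
        coef[idx] += df
        mate = (h % shape[0], k % shape[1], l % shape[2])
        coef[mate] += np.conj(df)
    n_tot = np.prod(shape)
    rho = np.real(np.fft.ifftn(coef)) * n_tot / structure.cell.volume
    return DensityGrid(values=rho, cell=structure.cell)


def deformation_map(
    structure: CrystalStructure,
    instructions: Sequence[Instruction],
    grid_spacing: float = 0.1,
    config: Optional[RefinementConfig] = None,
) -> DensityGrid:
    """Direct real-space sum of all placed deformation Gaussians.

    No Fourier truncation: each lobe contributes
    amp (4 pi / p)^{3/2} exp(-4 pi^2 r^2 / p) with p its reciprocal-space
    exponent, so the grid integral of any complete instruction set is zero.
    """
    cfg = config or RefinementConfig()
    shape = _grid_shape(structure.cell, grid_spacing)
    cell = structure.cell
    rho = np.zeros(shape)
    if not instructions:
        return DensityGrid(values=rho, cell=cell)
    connectivity = build_connectivity(structure)
    placed = expand_instructions(instructions, structure, connectivity)
    u_eq = {a.label: a.u_eq(cell) for a in structure.atoms}

    fx = np.arange(shape[0]) / shape[0]
    fy = np.arange(shape[1]) / shape[1]
    fz = np.arange(shape[2]) / shape[2]
    grid_frac = np.stack(np.meshgrid(fx, fy, fz, indexing="ij"), axis=-1)
    metric = cell.metric
    for g in placed:
        k_b = cfg.k_B1 if g.amplitude >= 0 else cfg.k_B2
        p = lobe_exponent(
            g.spread, u_eq[g.host_atom], k_B=k_b, additive=cfg.additive_spread_coupling
        )
        if p <= 0:
            raise ModelError(f"lobe from {g.origin!r}: non-positive exponent")
        d = grid_frac - g.center_frac
        d -= np.round(d)
        r2 = np.einsum("...i,ij,...j->...", d, metric, d)
        rho += (
            cfg.k_A
            * g.amplitude
            * (4.0 * math.pi / p) ** 1.5
            * np.exp(-4.0 * math.pi**2 * r2 / p)
        )
    return DensityGrid(values=rho, cell=cell)
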