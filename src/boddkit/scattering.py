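"""Analytic form factors and structure-factor assembly.

The scattering model is the four-Gaussian independent-atom form factor plus
optional deformation lobes (Gaussians placed in bonds and lone pairs whose
spreads are coupled to the host atom's displacement parameters). Structure
factors sum both contributions over the symmetry operations, so a model with
no lobes reduces exactly to the conventional spherical-atom calculation.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Union

import numpy as np

from .model import (
    Cell,
    CrystalStructure,
    GaussianCoefficients,
    ModelError,
    PlacedGaussian,
    RefinementConfig,
)

__all__ = [
    "iam_form_factor",
    "deformation_form_factor",
    "debye_waller",
    "structure_factor",
    "lobe_exponent",
]

TWO_PI = 2.0 * math.pi
EIGHT_PI_SQ = 8.0 * math.pi**2


def iam_form_factor(coeffs: GaussianCoefficients, s) -> Union[float, np.ndarray]:
    """Evaluate f(s) = sum_i a_i exp(-b_i s^2) + c.

    Parameters
    ----------
    coeffs
        Element coefficients (four amplitudes, four exponents, constant).
    s
        sin(theta)/lambda in 1/angstrom; scalar or array, must be >= 0.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ModelError("s = sin(theta)/lambda must be non-negative")
    s2 = s * s
    a = np.asarray(coeffs.a)
    b = np.asarray(coeffs.b)
    f = np.einsum("i,i...->...", a, np.exp(-np.multiply.outer(b, s2))) + coeffs.c
    return float(f) if f.ndim == 0 else f


def lobe_exponent(
    spread: float, host_u_eq: float, k_B: float = 1.0, additive: bool = False
) -> float:
    """Reciprocal-space exponent (coefficient of s^2) for a deformation lobe.

    Default (multiplicative) coupling: the spread B multiplies the host's
    isotropic Debye-Waller exponent, giving k_B * B * 8 pi^2 U_eq. The
    additive alternative uses k_B * B + 8 pi^2 U_eq.
    """
    if additive:
        return k_B * spread + EIGHT_PI_SQ * host_u_eq
    return k_B * spread * EIGHT_PI_SQ * host_u_eq


def deformation_form_factor(
    g: PlacedGaussian,
    s,
    host_u_eq: float,
    k_B: float = 1.0,
    additive: bool = False,
) -> Union[float, np.ndarray]:
    """Scattering contribution of one lobe: amplitude * exp(-expo * s^2)."""
    if host_u_eq <= 0:
        raise ModelError(
            f"host atom {g.host_atom!r}: U_eq must be positive for lobe coupling"
        )
    s = np.asarray(s, dtype=float)
    expo = lobe_exponent(g.spread, host_u_eq, k_B=k_B, additive=additive)
    f = g.amplitude * np.exp(-expo * s * s)
    return float(f) if f.ndim == 0 else f


def debye_waller(adp, hkl, cell: Cell) -> np.ndarray:
    """Debye-Waller factor per reflection.

    adp is either a scalar U_iso or the six components (U11, U22, U33, U23,
    U13, U12); isotropic gives exp(-8 pi^2 U s^2), anisotropic
    exp(-2 pi^2 h^T (N U N) h) with N = diag(a*, b*, c*).
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    if np.isscalar(adp) or np.ndim(adp) == 0:
        u = float(adp)
        if u < 0:
            raise ModelError("U_iso must be non-negative")
        s = cell.s_values(hkl)
        return np.exp(-EIGHT_PI_SQ * u * s * s)
    u11, u22, u33, u23, u13, u12 = np.asarray(adp, dtype=float)
    u = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
    n = np.diag(cell.reciprocal_lengths)
    ustar = n @ u @ n
    if np.linalg.eigvalsh(ustar).min() <= 0:
        raise ModelError("anisotropic U not positive definite")
    expo = 2.0 * math.pi**2 * np.einsum("ni,ij,nj->n", hkl, ustar, hkl)
    return np.exp(-expo)


def _atom_dw(atom, hr: np.ndarray, s2: np.ndarray, cell: Cell) -> np.ndarray:
    if atom.u_aniso is None:
        if atom.u_iso is None or atom.u_iso <= 0:
            raise ModelError(f"atom {atom.label}: missing/invalid displacement parameters")
        return np.exp(-EIGHT_PI_SQ * atom.u_iso * s2)
    ustar = atom.u_star_matrix(cell)
    expo = 2.0 * math.pi**2 * np.einsum("ni,ij,nj->n", hr, ustar, hr)
    return np.exp(-expo)


def structure_factor(
    structure: CrystalStructure,
    placed: Sequence[PlacedGaussian],
    config: RefinementConfig,
    hkl: Iterable[Sequence[int]],
) -> np.ndarray:
    """Complex structure factors F(h) for a list of Miller indices.

    F(h) = osf * sum_sym [ sum_atoms occ f_IAM(s) T(h) e^{2 pi i h.x}
                           + sum_lobes k_A amp e^{-expo s^2} e^{2 pi i h.x_lobe} ]

    where expo couples the lobe spread to the host atom's U_eq (scaled by
    k_B1 for positive-amplitude lobes, k_B2 for negative ones). With an
    empty lobe list this is the plain independent-atom calculation.
    """
    cell = structure.cell
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    s = cell.s_values(hkl)
    s2 = s * s

    # per-element form factors evaluated once
    f_elem = {
        el: iam_form_factor(coeffs, s) for el, coeffs in structure.sfac_table.items()
    }

    labels = set(structure.labels)
    for g in placed:
        if g.host_atom not in labels:
            raise ModelError(f"lobe references unknown host atom {g.host_atom!r}")
    u_eq = {a.label: a.u_eq(cell) for a in structure.atoms}
    for g in placed:
        if u_eq[g.host_atom] <= 0:
            raise ModelError(f"host atom {g.host_atom!r}: non-positive U_eq")

    total = np.zeros(len(hkl), dtype=complex)
    for op in structure.symmetry_ops:
        hr = hkl @ op.R  # transformed indices h.R
        ht = hkl @ op.t
        for atom in structure.atoms:
            phase = np.exp(TWO_PI * 1j * (hr @ atom.xyz + ht))
            dw = _atom_dw(atom, hr, s2, cell)
            total += atom.occupancy * f_elem[atom.element] * dw * phase
        if config.k_A != 0.0 and placed:
            for g in placed:
                k_b = config.k_B1 if g.amplitude >= 0 else config.k_B2
                expo = lobe_exponent(
                    g.spread, u_eq[g.host_atom], k_B=k_b,
                    additive=config.additive_spread_coupling,
                )
                phase = np.exp(TWO_PI * 1j * (hr @ g.center_frac + ht))
                total += config.k_A * g.amplitude * np.exp(-expo * s2) * phase
    return config.osf * total
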