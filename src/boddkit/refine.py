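"""Weighted least-squares refinement against Fo^2.

Refinable quantities are per-atom coordinates and displacement parameters,
the overall scale factor, and optionally the three global asphericity
scales k_A, k_B1, k_B2 that multiply all card A, B1 and B2 values.
Individual card parameters (r, A, B1, B2) never refine against experimental
data; they are fitted only against reference intensities from a target
density (``fit_archetype``).

Steps are damped Gauss-Newton (additive Marquardt parameter, x10 on
rejection, /3 on acceptance). The Jacobian is analytic for coordinates,
displacement parameters and the overall scale, and finite-difference for
the three asphericity scales. Riding hydrogens are repositioned from their
parents every cycle and contribute their derivatives to the parent columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .geometry_typing import (
    ConnectivityTable,
    build_connectivity,
    expand_instructions,
)
from .model import (
    BedeInstruction,
    CrystalStructure,
    Instruction,
    LoneInstruction,
    ModelError,
    PlacedGaussian,
    ReflectionSet,
    RefinementConfig,
)
from .scattering import EIGHT_PI_SQ, TWO_PI, iam_form_factor, lobe_exponent

__all__ = [
    "ParameterVector",
    "RefinementResult",
    "compute_weights",
    "ride_hydrogens",
    "refine",
    "fit_archetype",
]

_K_NAMES = ("k_A", "k_B1", "k_B2")


def compute_weights(fo2, sigma, fc2, a: float = 0.0, b: float = 0.0) -> np.ndarray:
    """SHELX-convention weights w = 1 / [sigma^2 + (aP)^2 + bP],
    P = (max(Fo^2, 0) + 2 Fc^2) / 3."""
    fo2 = np.asarray(fo2, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    fc2 = np.asarray(fc2, dtype=float)
    p = (np.maximum(fo2, 0.0) + 2.0 * fc2) / 3.0
    denom = sigma**2 + (a * p) ** 2 + b * p
    return 1.0 / np.maximum(denom, 1e-12)


def ride_hydrogens(
    structure: CrystalStructure,
    connectivity: Optional[ConnectivityTable] = None,
    elongation: float = 1.0,
) -> CrystalStructure:
    """Reposition riding H atoms at parent + elongation * ideal X-H vector.

    The ideal X-H distance is recorded on first application (from the input
    geometry) so repeated calls are idempotent. Mutates and returns the
    structure.
    """
    cell = structure.cell
    for atom in structure.atoms:
        if atom.riding_parent is None:
            continue
        if connectivity is not None:
            n_nb = len(connectivity.neighbors_of(atom.label))
            if n_nb == 0:
                raise ModelError(f"riding atom {atom.label} has no bonded parent")
            if n_nb > 1:
                raise ModelError(
                    f"riding atom {atom.label} has {n_nb} bonded neighbors; "
                    "exactly one parent required"
                )
        try:
            parent = structure.atom(atom.riding_parent)
        except KeyError:
            raise ModelError(
                f"riding atom {atom.label}: parent {atom.riding_parent!r} not found"
            )
        d = atom.xyz - parent.xyz
        d -= np.round(d)
        v = cell.frac_to_cart(d)
        dist = float(np.linalg.norm(v))
        if dist < 1e-6:
            raise ModelError(f"riding atom {atom.label} coincides with its parent")
        if atom.ideal_xh is None:
            atom.ideal_xh = dist
        new_cart = cell.frac_to_cart(parent.xyz) + elongation * atom.ideal_xh * (v / dist)
        atom.xyz = cell.cart_to_frac(new_cart)
    return structure


# ---------------------------------------------------------------------------
# parameter bookkeeping


@dataclass
class ParameterVector:
    """Ordered refinable quantities with extraction/injection.

    Layout: osf, then per-atom xyz (riding H excluded), then per-atom ADPs,
    then optionally the three global asphericity scales. Riding hydrogens
    are functions of their parents and never own coordinate entries.
    """

    entries: list[tuple] = field(default_factory=list)  # (kind, label, component)

    @classmethod
    def build(cls, structure: CrystalStructure, config: RefinementConfig) -> "ParameterVector":
        entries: list[tuple] = [("osf", None, 0)]
        for atom in structure.atoms:
            if atom.riding_parent is None:
                for j in range(3):
                    entries.append(("xyz", atom.label, j))
        for atom in structure.atoms:
            if atom.u_aniso is not None:
                for j in range(6):
                    entries.append(("uaniso", atom.label, j))
            else:
                entries.append(("uiso", atom.label, 0))
        if config.refine_k:
            for j in range(3):
                entries.append(("k", None, j))
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def index(self) -> dict[tuple, int]:
        return {e: i for i, e in enumerate(self.entries)}

    def extract(self, structure: CrystalStructure, config: RefinementConfig) -> np.ndarray:
        vals = np.empty(len(self.entries))
        for i, (kind, label, j) in enumerate(self.entries):
            if kind == "osf":
                vals[i] = config.osf
            elif kind == "xyz":
                vals[i] = structure.atom(label).xyz[j]
            elif kind == "uiso":
                vals[i] = structure.atom(label).u_iso
            elif kind == "uaniso":
                vals[i] = structure.atom(label).u_aniso[j]
            elif kind == "k":
                vals[i] = getattr(config, _K_NAMES[j])
        return vals

    def inject(
        self, values: np.ndarray, structure: CrystalStructure, config: RefinementConfig
    ) -> None:
        for i, (kind, label, j) in enumerate(self.entries):
            v = float(values[i])
            if kind == "osf":
                config.osf = max(v, 1e-8)
            elif kind == "xyz":
                structure.atom(label).xyz[j] = v
            elif kind == "uiso":
                structure.atom(label).u_iso = max(v, 1e-6)
            elif kind == "uaniso":
                structure.atom(label).u_aniso[j] = v
            elif kind == "k":
                setattr(config, _K_NAMES[j], min(max(v, 0.0), 10.0))


@dataclass
class RefinementResult:
    structure: CrystalStructure
    config: RefinementConfig
    converged: bool
    cycles: int
    r1: float
    wr2: float
    goof: float
    shifts: np.ndarray
    esds: np.ndarray
    parameters: ParameterVector
    history: list[dict] = field(default_factory=list)
    fc: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# model + jacobian


def _ueq_coeffs(structure, atom) -> np.ndarray:
    """dU_eq/dU_j for the six (U11,U22,U33,U23,U13,U12) components."""
    g = structure.cell.metric
    rl = structure.cell.reciprocal_lengths
    return np.array(
        [
            g[0, 0] * rl[0] ** 2,
            g[1, 1] * rl[1] ** 2,
            g[2, 2] * rl[2] ** 2,
            2.0 * g[1, 2] * rl[1] * rl[2],
            2.0 * g[0, 2] * rl[0] * rl[2],
            2.0 * g[0, 1] * rl[0] * rl[1],
        ]
    ) / 3.0


def _expand_lobes(structure, instructions, connectivity) -> list[PlacedGaussian]:
    if not instructions:
        return []
    return expand_instructions(instructions, structure, connectivity)


def _lobe_sum(structure, placed, config, hkl, s2) -> np.ndarray:
    """Unscaled lobe contribution sum (without osf)."""
    if not placed or config.k_A == 0.0:
        return np.zeros(len(hkl), dtype=complex)
    cell = structure.cell
    u_eq = {a.label: a.u_eq(cell) for a in structure.atoms}
    total = np.zeros(len(hkl), dtype=complex)
    for op in structure.symmetry_ops:
        hr = hkl @ op.R
        ht = hkl @ op.t
        for g in placed:
            k_b = config.k_B1 if g.amplitude >= 0 else config.k_B2
            expo = lobe_exponent(
                g.spread, u_eq[g.host_atom], k_B=k_b,
                additive=config.additive_spread_coupling,
            )
            phase = np.exp(TWO_PI * 1j * (hr @ g.center_frac + ht))
            total += config.k_A * g.amplitude * np.exp(-expo * s2) * phase
    return total


def _model_and_jacobian(
    structure: CrystalStructure,
    placed: Sequence[PlacedGaussian],
    config: RefinementConfig,
    hkl: np.ndarray,
    pvec: ParameterVector,
):
    """Return (F complex, d|F|^2/dp matrix)."""
    cell = structure.cell
    n = len(hkl)
    s = cell.s_values(hkl)
    s2 = s * s
    col = pvec.index()
    n_par = len(pvec)
    f_elem = {el: iam_form_factor(c, s) for el, c in structure.sfac_table.items()}
    rl = cell.reciprocal_lengths
    use_lobes = bool(placed) and (config.k_A != 0.0 or config.refine_k)

    # coordinate derivatives route through the riding parent where applicable
    def xyz_target(label: str) -> Optional[str]:
        atom = structure.atom(label)
        lbl = atom.riding_parent if atom.riding_parent is not None else label
        return lbl if ("xyz", lbl, 0) in col else None

    u_eq = {a.label: a.u_eq(cell) for a in structure.atoms}
    ueq_c = {
        a.label: (_ueq_coeffs(structure, a) if a.u_aniso is not None else None)
        for a in structure.atoms
    }

    s_total = np.zeros(n, dtype=complex)
    ds = np.zeros((n, n_par), dtype=complex)

    for op in structure.symmetry_ops:
        hr = hkl @ op.R
        ht = hkl @ op.t
        # anisotropic quadratic-form coefficients per reflection
        qc = 2.0 * math.pi**2 * np.stack(
            [
                hr[:, 0] ** 2 * rl[0] ** 2,
                hr[:, 1] ** 2 * rl[1] ** 2,
                hr[:, 2] ** 2 * rl[2] ** 2,
                2.0 * hr[:, 1] * hr[:, 2] * rl[1] * rl[2],
                2.0 * hr[:, 0] * hr[:, 2] * rl[0] * rl[2],
                2.0 * hr[:, 0] * hr[:, 1] * rl[0] * rl[1],
            ],
            axis=1,
        )
        for atom in structure.atoms:
            phase = np.exp(TWO_PI * 1j * (hr @ atom.xyz + ht))
            if atom.u_aniso is not None:
                dw = np.exp(-(qc @ atom.u_aniso))
            else:
                dw = np.exp(-EIGHT_PI_SQ * atom.u_iso * s2)
            term = atom.occupancy * f_elem[atom.element] * dw * phase
            s_total += term
            tgt = xyz_target(atom.label)
            if tgt is not None:
                for j in range(3):
                    ds[:, col[("xyz", tgt, j)]] += term * (TWO_PI * 1j * hr[:, j])
            if atom.u_aniso is not None:
                for j in range(6):
                    ds[:, col[("uaniso", atom.label, j)]] += term * (-qc[:, j])
            else:
                ds[:, col[("uiso", atom.label, 0)]] += term * (-EIGHT_PI_SQ * s2)
        if use_lobes and config.k_A != 0.0:
            for g in placed:
                k_b = config.k_B1 if g.amplitude >= 0 else config.k_B2
                expo = lobe_exponent(
                    g.spread, u_eq[g.host_atom], k_B=k_b,
                    additive=config.additive_spread_coupling,
                )
                phase = np.exp(TWO_PI * 1j * (hr @ g.center_frac + ht))
                term = config.k_A * g.amplitude * np.exp(-expo * s2) * phase
                s_total += term
                tgt = xyz_target(g.host_atom)
                if tgt is not None:
                    for j in range(3):
                        ds[:, col[("xyz", tgt, j)]] += term * (TWO_PI * 1j * hr[:, j])
                # spread couples to the host's U_eq
                if config.additive_spread_coupling:
                    dexpo_dueq = EIGHT_PI_SQ
                else:
                    dexpo_dueq = k_b * g.spread * EIGHT_PI_SQ
                host = structure.atom(g.host_atom)
                if host.u_aniso is not None:
                    cu = ueq_c[g.host_atom]
                    for j in range(6):
                        ds[:, col[("uaniso", g.host_atom, j)]] += term * (
                            -dexpo_dueq * s2 * cu[j]
                        )
                else:
                    ds[:, col[("uiso", g.host_atom, 0)]] += term * (-dexpo_dueq * s2)

    f_total = config.osf * s_total
    jac = np.zeros((n, n_par))
    # d|F|^2/dp = 2 Re(conj(F) * osf * dS/dp) for structural parameters
    jac += 2.0 * np.real(np.conj(f_total)[:, None] * (config.osf * ds))
    jac[:, col[("osf", None, 0)]] = 2.0 * config.osf * np.abs(s_total) ** 2

    if config.refine_k and placed:
        # finite differences on the lobe part only
        base_atoms = s_total - _lobe_sum(structure, placed, config, hkl, s2)
        for j, name in enumerate(_K_NAMES):
            delta = 1e-5 * max(1.0, abs(getattr(config, name)))
            for sign in (+1.0, -1.0):
                cfg = config.copy()
                setattr(cfg, name, getattr(config, name) + sign * delta)
                st = base_atoms + _lobe_sum(structure, placed, cfg, hkl, s2)
                jac[:, col[("k", None, j)]] += (
                    sign * np.abs(config.osf * st) ** 2 / (2.0 * delta)
                )
    return f_total, jac


# ---------------------------------------------------------------------------
# the refinement driver


def refine(
    structure: CrystalStructure,
    instructions: Sequence[Instruction],
    reflections: ReflectionSet,
    config: RefinementConfig,
    free_mask: Optional[np.ndarray] = None,
    apply_riding: bool = True,
) -> RefinementResult:
    """Minimize sum w (Fo^2 - |Fc|^2)^2 over the working reflections.

    ``free_mask`` marks reflections excluded from the working set (they take
    no part in the fit; used for cross-validation). Statistics are reported
    on the working set.
    """
    struct = structure.copy()
    cfg = config.copy()
    hkl = np.asarray(reflections.hkl, dtype=float)
    if free_mask is not None:
        work = ~np.asarray(free_mask, dtype=bool)
    else:
        work = np.ones(len(reflections), dtype=bool)
    if work.sum() == 0:
        raise ModelError("empty working set")
    fo2 = reflections.fo2
    sigma = reflections.sigma

    connectivity = build_connectivity(struct)
    pvec = ParameterVector.build(struct, cfg)
    if work.sum() <= len(pvec):
        raise ModelError(
            f"data-to-parameter ratio too low: {int(work.sum())} reflections "
            f"for {len(pvec)} parameters"
        )

    def model(st: CrystalStructure, cf: RefinementConfig):
        if apply_riding:
            ride_hydrogens(st, None, cf.elongation)
        placed = (
            _expand_lobes(st, instructions, connectivity)
            if instructions and (cf.k_A != 0.0 or cf.refine_k)
            else []
        )
        return placed

    # floating-origin handling: in P1 the structure-factor moduli are
    # invariant under a uniform translation, so the per-axis mean coordinate
    # shift is projected out of every step (the conventional restraint).
    origin_free = len(struct.symmetry_ops) == 1
    col_idx = pvec.index()
    xyz_cols = [
        [col_idx[e] for e in pvec.entries if e[0] == "xyz" and e[2] == j]
        for j in range(3)
    ]

    def _project_origin(delta: np.ndarray) -> np.ndarray:
        if origin_free:
            for cols in xyz_cols:
                if cols:
                    delta[cols] -= np.mean(delta[cols])
        return delta

    lam = 0.0
    converged = False
    cycles_used = 0
    history: list[dict] = []
    shifts = np.zeros(len(pvec))
    esds = np.full(len(pvec), np.nan)
    jac = None
    fvals = None

    for cycle in range(1, cfg.max_cycles + 1):
        cycles_used = cycle
        placed = model(struct, cfg)
        fvals, jac = _model_and_jacobian(struct, placed, cfg, hkl, pvec)
        fc2 = np.abs(fvals) ** 2
        w = compute_weights(fo2, sigma, fc2, cfg.weight_a, cfg.weight_b)
        resid = fo2 - fc2
        ssr = float(np.sum(w[work] * resid[work] ** 2))

        jw = jac[work] * np.sqrt(w[work])[:, None]
        rw = resid[work] * np.sqrt(w[work])
        normal = jw.T @ jw
        rhs = jw.T @ rw
        diag_scale = np.maximum(np.diag(normal), 1e-12)

        accepted = False
        for _attempt in range(12):
            try:
                delta = np.linalg.solve(
                    normal + lam * np.diag(diag_scale), rhs
                )
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-7)
                continue
            delta = _project_origin(delta)
            trial_struct = struct.copy()
            trial_cfg = cfg.copy()
            vals = pvec.extract(struct, cfg) + delta
            pvec.inject(vals, trial_struct, trial_cfg)
            try:
                trial_placed = model(trial_struct, trial_cfg)
                trial_f, _ = _model_and_jacobian(
                    trial_struct, trial_placed, trial_cfg, hkl, pvec
                )
            except (ModelError, np.linalg.LinAlgError):
                lam = max(lam * 10.0, 1e-7)
                continue
            trial_resid = fo2 - np.abs(trial_f) ** 2
            trial_ssr = float(np.sum(w[work] * trial_resid[work] ** 2))
            if trial_ssr <= ssr + 1e-14 * max(ssr, 1.0):
                struct, cfg = trial_struct, trial_cfg
                shifts = delta
                lam /= 3.0
                if lam < 1e-12:
                    lam = 0.0
                accepted = True
                break
            lam = max(lam * 10.0, 1e-7)
        if not accepted:
            # cannot improve: treat as converged at the current point
            shifts = np.zeros(len(pvec))

        # statistics and convergence check on the accepted model
        placed = model(struct, cfg)
        fvals, jac = _model_and_jacobian(struct, placed, cfg, hkl, pvec)
        fc2 = np.abs(fvals) ** 2
        w = compute_weights(fo2, sigma, fc2, cfg.weight_a, cfg.weight_b)
        resid = fo2 - fc2
        n_work = int(work.sum())
        dof = max(n_work - len(pvec), 1)
        goof = math.sqrt(float(np.sum(w[work] * resid[work] ** 2)) / dof)
        esds = _esds(jac[work], w[work], goof)
        with np.errstate(divide="ignore", invalid="ignore"):
            # esd floor keeps the ratio finite at a perfect fit (0/0)
            shift_esd = np.abs(shifts) / np.maximum(
                np.nan_to_num(esds, nan=0.0), 1e-8
            )
        max_shift = float(np.max(shift_esd)) if len(shift_esd) else 0.0
        r1, wr2 = _r_stats(fo2[work], sigma[work], fc2[work], w[work])
        history.append(
            {"cycle": cycle, "r1": r1, "wr2": wr2, "max_shift_esd": max_shift,
             "ssr": float(np.sum(w[work] * resid[work] ** 2))}
        )
        if max_shift < cfg.convergence_tol:
            converged = True
            break

    fc2 = np.abs(fvals) ** 2
    w = compute_weights(fo2, sigma, fc2, cfg.weight_a, cfg.weight_b)
    n_work = int(work.sum())
    dof = max(n_work - len(pvec), 1)
    goof = math.sqrt(float(np.sum(w[work] * (fo2 - fc2)[work] ** 2)) / dof)
    r1, wr2 = _r_stats(fo2[work], sigma[work], fc2[work], w[work])
    return RefinementResult(
        structure=struct,
        config=cfg,
        converged=converged,
        cycles=cycles_used,
        r1=r1,
        wr2=wr2,
        goof=goof,
        shifts=shifts,
        esds=esds,
        parameters=pvec,
        history=history,
        fc=fvals,
    )


def _esds(jw_raw: np.ndarray, w: np.ndarray, goof: float) -> np.ndarray:
    jw = jw_raw * np.sqrt(w)[:, None]
    normal = jw.T @ jw
    try:
        cov = np.linalg.pinv(normal)
    except np.linalg.LinAlgError:
        return np.full(jw.shape[1], np.nan)
    diag = np.clip(np.diag(cov), 0.0, None)
    return goof * np.sqrt(diag)


def _r_stats(fo2, sigma, fc2, w) -> tuple[float, float]:
    strong = fo2 > 2.0 * sigma
    if strong.sum() == 0:
        strong = np.ones_like(fo2, dtype=bool)
    fo = np.sqrt(np.maximum(fo2[strong], 0.0))
    fc = np.sqrt(fc2[strong])
    r1 = float(np.sum(np.abs(fo - fc)) / max(np.sum(fo), 1e-12))
    wr2 = float(
        math.sqrt(np.sum(w * (fo2 - fc2) ** 2) / max(np.sum(w * fo2**2), 1e-12))
    )
    return r1, wr2


# ---------------------------------------------------------------------------
# archetype parameter fitting (toy-scale stand-in for database generation)


def fit_archetype(
    reference_reflections: ReflectionSet,
    instruction_skeletons: Sequence[Instruction],
    structure: CrystalStructure,
    method: str = "differential_evolution",
    seed: int = 0,
    maxiter: int = 40,
    config: Optional[RefinementConfig] = None,
) -> tuple[list[Instruction], dict]:
    """Fit per-card (r, A, B1, B2) against reference intensities.

    The reference data stand in for intensities Fourier-transformed from a
    target electron density. Bounded global search (differential evolution)
    followed by local polish; deterministic under ``seed``.
    """
    cfg = (config or RefinementConfig()).copy()
    connectivity = build_connectivity(structure)
    hkl = np.asarray(reference_reflections.hkl, dtype=float)
    fo2 = reference_reflections.fo2
    w = 1.0 / reference_reflections.sigma**2
    s2 = structure.cell.s_values(hkl) ** 2

    bounds: list[tuple[float, float]] = []
    for _ in instruction_skeletons:
        bounds.extend([(0.05, 1.5), (-2.0, 2.0), (0.05, 5.0), (0.05, 5.0)])

    def build(x: np.ndarray) -> list[Instruction]:
        out: list[Instruction] = []
        for i, skel in enumerate(instruction_skeletons):
            r, a, b1, b2 = x[4 * i: 4 * i + 4]
            if isinstance(skel, BedeInstruction):
                out.append(BedeInstruction(skel.atom1, skel.atom2, r, a, b1, b2))
            else:
                out.append(
                    LoneInstruction(skel.m, skel.atom, a, b1, b2, r, skel.angle)
                )
        return out

    base = np.zeros(len(hkl), dtype=complex)
    # IAM part is constant during the search
    from .scattering import structure_factor

    iam_cfg = cfg.copy()
    iam_cfg.k_A = 0.0
    base = structure_factor(structure, [], iam_cfg, hkl) / iam_cfg.osf

    def objective(x: np.ndarray) -> float:
        try:
            placed = expand_instructions(build(x), structure, connectivity)
        except ModelError:
            return 1e12
        lobes = _lobe_sum(structure, placed, cfg, hkl, s2)
        fc2 = np.abs(cfg.osf * (base + lobes)) ** 2
        return float(np.sum(w * (fo2 - fc2) ** 2))

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            placed = expand_instructions(build(x), structure, connectivity)
        except ModelError:
            return np.full(len(hkl), 1e6)
        lobes = _lobe_sum(structure, placed, cfg, hkl, s2)
        fc2 = np.abs(cfg.osf * (base + lobes)) ** 2
        return np.sqrt(w) * (fo2 - fc2)

    if method not in ("differential_evolution", "de"):
        raise ModelError(f"unknown search method {method!r}")
    result = optimize.differential_evolution(
        objective,
        bounds,
        seed=seed,
        maxiter=maxiter,
        tol=1e-12,
        polish=False,
        init="sobol",
        updating="deferred",
    )
    x_best, f_best = result.x, float(result.fun)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    local = optimize.least_squares(
        residuals, np.clip(x_best, lo, hi), bounds=(lo, hi),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    nfev = int(result.nfev) + int(local.nfev)
    if float(local.cost) * 2.0 <= f_best:
        x_best, f_best = local.x, float(local.cost) * 2.0
    info = {
        "objective": f_best,
        "nfev": nfev,
        "budget_exhausted": not (result.success or local.success),
    }
    return build(x_best), info
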