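"""Readers and writers for SHELX-style structure and reflection files.

Supported cards: TITL, CELL, ZERR, LATT, SYMM, SFAC (element shorthand or
full coefficient form), UNIT, FVAR, WGHT, L.S., AFIX, atom records with the
10+x fixed-parameter convention on occupancies, and the deformation cards
BEDE / LONE. Two dialect cards are added for round-tripping toolkit state:
``KSCL kA kB1 kB2`` (global asphericity scales), ``ELON x`` (riding-H
elongation) and ``RIDE h parent [ideal]`` (riding-H bookkeeping). A
``BODD filename`` card pulls BEDE/LONE cards from an external file with one
whitespace-delimited card per line, same token order as inline cards.

Unknown benign keywords are preserved verbatim so files round-trip.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .data import form_factor_coefficients
from .model import (
    AtomSite,
    BedeInstruction,
    Cell,
    CrystalStructure,
    GaussianCoefficients,
    Instruction,
    LoneInstruction,
    ModelError,
    ReflectionSet,
    RefinementConfig,
    SymmetryOp,
)

__all__ = ["read_ins", "read_ins_file", "write_res", "read_hkl", "write_hkl", "write_fcf"]


class ParseError(ModelError):
    pass


# SHELX keywords we recognise but deliberately pass through (or warn about).
_PASSTHROUGH = {
    "REM", "MORE", "ACTA", "BOND", "CONF", "FMAP", "PLAN", "LIST", "SIZE",
    "TEMP", "MPLA", "HTAB", "EQIV", "DFIX", "SADI", "SIMU", "RIGU", "DELU",
    "ISOR", "FLAT", "CHIV", "SHEL", "OMIT", "GRID", "MOLE", "SPEC", "STIR",
    "DAMP", "WPDB", "BIND", "FREE", "CONN", "PART", "SUMP", "EADP", "EXYZ",
}
_WARN_IGNORED = {"TWIN", "BASF", "EXTI", "SWAT", "DISP", "ANIS", "MERG"}
_STRUCTURAL = {
    "TITL", "CELL", "ZERR", "LATT", "SYMM", "SFAC", "UNIT", "FVAR", "WGHT",
    "L.S.", "CGLS", "AFIX", "HFIX", "BEDE", "LONE", "KSCL", "ELON", "RIDE",
    "BODD", "HKLF", "END",
}

_LATT_CENTERING = {
    1: [(0.0, 0.0, 0.0)],
    2: [(0.0, 0.0, 0.0), (0.5, 0.5, 0.5)],
    3: [(0.0, 0.0, 0.0), (2 / 3, 1 / 3, 1 / 3), (1 / 3, 2 / 3, 2 / 3)],
    4: [(0.0, 0.0, 0.0), (0.0, 0.5, 0.5), (0.5, 0.0, 0.5), (0.5, 0.5, 0.0)],
    5: [(0.0, 0.0, 0.0), (0.0, 0.5, 0.5)],
    6: [(0.0, 0.0, 0.0), (0.5, 0.0, 0.5)],
    7: [(0.0, 0.0, 0.0), (0.5, 0.5, 0.0)],
}


def _parse_symm(expr: str) -> SymmetryOp:
    rows = []
    trans = []
    parts = expr.upper().replace(" ", "").split(",")
    if len(parts) != 3:
        raise ParseError(f"SYMM needs three components: {expr!r}")
    for part in parts:
        row = [0.0, 0.0, 0.0]
        t = 0.0
        for sign, coef, var, num, den in re.findall(
            r"([+-]?)(\d*\.?\d*)\*?([XYZ])|([+-]?\d+\.?\d*)(?:/(\d+))?", part
        ):
            if var:
                c = float(coef) if coef else 1.0
                if sign == "-":
                    c = -c
                row["XYZ".index(var)] += c
            elif num:
                val = float(num)
                if den:
                    val /= float(den)
                t += val
        rows.append(tuple(row))
        trans.append(t)
    return SymmetryOp(rotation=tuple(rows), translation=tuple(trans))


def _format_symm(op: SymmetryOp) -> str:
    parts = []
    for i in range(3):
        terms = []
        for j, var in enumerate("XYZ"):
            c = op.R[i, j]
            if abs(c) < 1e-9:
                continue
            sign = "-" if c < 0 else ("+" if terms else "")
            mag = abs(c)
            terms.append(f"{sign}{'' if abs(mag - 1) < 1e-9 else f'{mag:g}*'}{var}")
        t = op.t[i]
        if abs(t) > 1e-9:
            terms.append(f"{'+' if t > 0 else '-'}{abs(t):g}")
        parts.append("".join(terms) or "0")
    return ", ".join(parts)


def _decode_fixed(value: float) -> float:
    """SHELX 10+x convention: parameters coded above 5 are fixed at value-10."""
    return value - 10.0 if value > 5.0 else value


def parse_card(tokens: Sequence[str]) -> Instruction:
    """Parse one BEDE/LONE card from its whitespace tokens."""
    key = tokens[0].upper()
    if key == "BEDE":
        if len(tokens) != 7:
            raise ParseError(f"BEDE needs 6 arguments: {' '.join(tokens)}")
        a1, a2 = tokens[1], tokens[2]
        r, A, b1, b2 = map(float, tokens[3:7])
        return BedeInstruction(a1, a2, r, A, b1, b2)
    if key == "LONE":
        if len(tokens) not in (7, 8):
            raise ParseError(f"LONE needs 6 or 7 arguments: {' '.join(tokens)}")
        m = int(tokens[1])
        atom = tokens[2]
        A, b1, b2, r = map(float, tokens[3:7])
        angle = float(tokens[7]) if len(tokens) == 8 else None
        return LoneInstruction(m, atom, A, b1, b2, r, angle)
    raise ParseError(f"not an instruction card: {' '.join(tokens)}")


def read_ins(
    text: str,
    external_loader: Optional[Callable[[str], str]] = None,
) -> tuple[CrystalStructure, list[Instruction], RefinementConfig]:
    """Parse an INS/RES character stream.

    ``external_loader`` maps the filename on a ``BODD file`` card to its
    contents; required only when such a card is present.
    """
    # join continuation lines (trailing '=')
    lines: list[str] = []
    pending = ""
    for raw in text.splitlines():
        stripped = raw.rstrip()
        if pending:
            stripped = pending + " " + stripped.strip()
            pending = ""
        if stripped.endswith("="):
            pending = stripped[:-1]
            continue
        lines.append(stripped)
    if pending:
        lines.append(pending)

    title = ""
    cell: Optional[Cell] = None
    wavelength = 0.71073
    latt = -1
    symm_ops: list[SymmetryOp] = []
    sfac_labels: list[str] = []
    sfac_table: dict[str, GaussianCoefficients] = {}
    atoms: list[AtomSite] = []
    cards: list[Instruction] = []
    card_tokens: list[tuple[list[str], int]] = []
    config_kw: dict = {}
    extra: list[str] = []
    ride_info: list[tuple[str, str, Optional[float]]] = []
    afix_parent: Optional[str] = None
    in_afix = False

    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        tokens = line.split()
        key = tokens[0][:4].upper()
        if key == "TITL":
            title = line[4:].strip()
        elif key == "CELL":
            vals = list(map(float, tokens[1:8]))
            if len(vals) != 7:
                raise ParseError(f"line {lineno}: CELL needs wavelength + 6 parameters")
            wavelength = vals[0]
            cell = Cell(*vals[1:])
        elif key == "ZERR":
            extra.append(line)
        elif key == "LATT":
            latt = int(tokens[1])
        elif key == "SYMM":
            symm_ops.append(_parse_symm(line[4:]))
        elif key == "SFAC":
            if len(tokens) >= 11 and _is_float(tokens[2]):
                label = tokens[1].capitalize()
                vals = list(map(float, tokens[2:11]))
                sfac_table[label] = GaussianCoefficients(
                    a=tuple(vals[0:8:2]), b=tuple(vals[1:8:2]), c=vals[8]
                )
                sfac_labels.append(label)
            else:
                for el in tokens[1:]:
                    label = el.capitalize()
                    sfac_table[label] = form_factor_coefficients(label)
                    sfac_labels.append(label)
        elif key == "UNIT":
            pass  # recomputed from the atom list on write
        elif key == "FVAR":
            config_kw["osf"] = float(tokens[1])
        elif key == "WGHT":
            config_kw["weight_a"] = float(tokens[1])
            if len(tokens) > 2:
                config_kw["weight_b"] = float(tokens[2])
        elif key in ("L.S.", "CGLS"):
            config_kw["max_cycles"] = max(1, int(tokens[1]))
        elif key == "KSCL":
            config_kw["k_A"], config_kw["k_B1"], config_kw["k_B2"] = map(float, tokens[1:4])
        elif key == "ELON":
            config_kw["elongation"] = float(tokens[1])
        elif key == "BEDE" or key == "LONE":
            card_tokens.append((tokens, lineno))
        elif key == "BODD":
            if external_loader is None:
                raise ParseError(
                    f"line {lineno}: BODD references external file {tokens[1]!r} "
                    "but no loader was provided"
                )
            for sub_no, sub in enumerate(external_loader(tokens[1]).splitlines(), start=1):
                sub = sub.strip()
                if sub and not sub.startswith("#") and not sub.upper().startswith("REM"):
                    card_tokens.append((sub.split(), sub_no))
        elif key == "RIDE":
            ideal = float(tokens[3]) if len(tokens) > 3 else None
            ride_info.append((tokens[1], tokens[2], ideal))
        elif key == "AFIX":
            code = int(tokens[1])
            in_afix = code != 0
        elif key == "HKLF" or key == "END":
            break
        elif key in _WARN_IGNORED:
            warnings.warn(f"card {key} parsed and ignored: {line}")
            extra.append(line)
        elif key in _PASSTHROUGH:
            extra.append(line)
        elif key in _STRUCTURAL:
            raise ParseError(f"line {lineno}: malformed {key} card: {line}")
        else:
            atom = _parse_atom(tokens, sfac_labels, lineno)
            if atom is None:
                extra.append(line)
                continue
            if atom.element != "H":
                afix_parent = atom.label
            elif in_afix and afix_parent is not None:
                atom.riding_parent = afix_parent
            atoms.append(atom)

    if cell is None:
        raise ParseError("missing CELL card")
    if not atoms:
        raise ParseError("no atom records found")
    for h_label, parent, ideal in ride_info:
        for atom in atoms:
            if atom.label == h_label:
                atom.riding_parent = parent
                atom.ideal_xh = ideal
                break
        else:
            raise ParseError(f"RIDE names unknown atom {h_label!r}")

    ops = _expand_symmetry(symm_ops, latt)
    structure = CrystalStructure(
        cell=cell,
        atoms=atoms,
        sfac_table=sfac_table,
        symmetry_ops=ops,
        wavelength=wavelength,
        title=title,
        extra_cards=extra,
    )

    labels = set(structure.labels)
    for tokens, lineno in card_tokens:
        instr = parse_card(tokens)
        named = (
            [instr.atom1, instr.atom2]
            if isinstance(instr, BedeInstruction)
            else [instr.atom]
        )
        unknown = [l for l in named if l not in labels]
        if unknown:
            raise ParseError(
                f"line {lineno}: {tokens[0].upper()} names unknown atom "
                f"label(s) {unknown}"
            )
        cards.append(instr)

    config = RefinementConfig(**config_kw) if config_kw else RefinementConfig()
    return structure, cards, config


def read_ins_file(path) -> tuple[CrystalStructure, list[Instruction], RefinementConfig]:
    path = Path(path)

    def loader(name: str) -> str:
        return (path.parent / name).read_text()

    return read_ins(path.read_text(), external_loader=loader)


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _parse_atom(tokens, sfac_labels, lineno) -> Optional[AtomSite]:
    if len(tokens) < 5 or not tokens[1].isdigit():
        return None
    if not all(_is_float(t) for t in tokens[2:]):
        raise ParseError(f"line {lineno}: non-numeric field in atom record: {' '.join(tokens)}")
    idx = int(tokens[1])
    if not 1 <= idx <= len(sfac_labels):
        raise ParseError(f"line {lineno}: SFAC index {idx} out of range")
    vals = list(map(float, tokens[2:]))
    xyz = vals[0:3]
    occ = _decode_fixed(vals[3]) if len(vals) > 3 else 1.0
    rest = vals[4:]
    u_iso = None
    u_aniso = None
    if len(rest) >= 6:
        u_aniso = rest[0:6]
    elif len(rest) >= 1:
        u_iso = rest[0]
    else:
        u_iso = 0.05
    return AtomSite(
        label=tokens[0],
        element=sfac_labels[idx - 1],
        xyz=np.array(xyz),
        occupancy=occ,
        u_iso=u_iso,
        u_aniso=None if u_aniso is None else np.array(u_aniso),
    )


def _expand_symmetry(symm_ops, latt) -> list[SymmetryOp]:
    base = [SymmetryOp.identity()] + list(symm_ops)
    centering = _LATT_CENTERING.get(abs(latt))
    if centering is None:
        raise ParseError(f"unsupported LATT {latt}")
    ops = []
    seen = set()

    def _add(rot, tr):
        tr = tuple(round(float(t) % 1.0, 9) for t in tr)
        key = (tuple(map(tuple, np.round(rot, 9))), tr)
        if key not in seen:
            seen.add(key)
            ops.append(SymmetryOp(rotation=tuple(map(tuple, rot)), translation=tr))

    for op in base:
        mats = [(op.R, op.t)]
        if latt > 0:  # centrosymmetric
            mats.append((-op.R, -op.t))
        for rot, tr in mats:
            for cv in centering:
                _add(rot, tr + np.asarray(cv))
    return ops


# ---------------------------------------------------------------------------
# writing


def write_res(
    structure: CrystalStructure,
    instructions: Sequence[Instruction] = (),
    config: Optional[RefinementConfig] = None,
) -> str:
    """Serialize a structure (plus cards and config) back to INS/RES text.

    ``read_ins(write_res(x))`` reproduces x up to floating-point formatting.
    """
    config = config or RefinementConfig()
    c = structure.cell
    out = [f"TITL {structure.title}".rstrip()]
    out.append(
        f"CELL {structure.wavelength:.5f} {c.a:.6f} {c.b:.6f} {c.c:.6f} "
        f"{c.alpha:.4f} {c.beta:.4f} {c.gamma:.4f}"
    )
    out.append("LATT -1")
    for op in structure.symmetry_ops:
        if not op.is_identity:
            out.append(f"SYMM {_format_symm(op)}")
    labels = sorted(structure.sfac_table)
    for el in labels:
        gc = structure.sfac_table[el]
        coeffs = " ".join(
            f"{v:.6f}" for pair in zip(gc.a, gc.b) for v in pair
        )
        out.append(f"SFAC {el} {coeffs} {gc.c:.6f} 0 0 0 0 1")
    counts = {el: 0 for el in labels}
    for atom in structure.atoms:
        counts[atom.element] += 1
    out.append("UNIT " + " ".join(str(counts[el]) for el in labels))
    out.extend(structure.extra_cards)
    out.append(f"L.S. {config.max_cycles}")
    out.append(f"WGHT {config.weight_a:.6f} {config.weight_b:.6f}")
    out.append(f"FVAR {config.osf:.6f}")
    out.append(f"KSCL {config.k_A:.6f} {config.k_B1:.6f} {config.k_B2:.6f}")
    out.append(f"ELON {config.elongation:.6f}")
    for instr in instructions:
        out.append(instr.to_card())
    sfac_index = {el: i + 1 for i, el in enumerate(labels)}
    for atom in structure.atoms:
        fields = [
            atom.label,
            str(sfac_index[atom.element]),
            f"{atom.xyz[0]:.6f}",
            f"{atom.xyz[1]:.6f}",
            f"{atom.xyz[2]:.6f}",
            f"{atom.occupancy + 10.0:.6f}",
        ]
        if atom.u_aniso is not None:
            fields += [f"{u:.6f}" for u in atom.u_aniso]
        else:
            fields.append(f"{atom.u_iso:.6f}")
        out.append(" ".join(fields))
    for atom in structure.atoms:
        if atom.riding_parent is not None:
            card = f"RIDE {atom.label} {atom.riding_parent}"
            if atom.ideal_xh is not None:
                card += f" {atom.ideal_xh:.6f}"
            out.append(card)
    out.append("HKLF 4")
    out.append("END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# reflections


def read_hkl(text: str, cell: Optional[Cell] = None) -> ReflectionSet:
    """Parse HKLF 4 reflection data (fixed width 3I4 + 2F8).

    Equivalent (identical-index) reflections are merged by weighted mean;
    non-positive sigmas are excluded with a warning. A 0 0 0 terminator row
    stops parsing. If ``cell`` is given, s = sin(theta)/lambda is attached.
    """
    rows: list[tuple[int, int, int, float, float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            if len(line) >= 28:
                h, k, l = int(line[0:4]), int(line[4:8]), int(line[8:12])
                fo2, sig = float(line[12:20]), float(line[20:28])
            else:
                tokens = line.split()
                h, k, l = int(tokens[0]), int(tokens[1]), int(tokens[2])
                fo2, sig = float(tokens[3]), float(tokens[4])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"HKL line {lineno}: cannot parse {line!r}") from exc
        if h == 0 and k == 0 and l == 0:
            break
        if sig <= 0:
            warnings.warn(f"HKL line {lineno}: sigma <= 0, reflection ({h} {k} {l}) excluded")
            continue
        rows.append((h, k, l, fo2, sig))
    if not rows:
        raise ParseError("no reflections in HKL data")

    merged: dict[tuple[int, int, int], list[tuple[float, float]]] = {}
    for h, k, l, fo2, sig in rows:
        merged.setdefault((h, k, l), []).append((fo2, sig))
    hkl, fo2s, sigs = [], [], []
    for key, obs in merged.items():
        w = np.array([1.0 / s**2 for _, s in obs])
        f = np.array([f for f, _ in obs])
        hkl.append(key)
        fo2s.append(float(np.sum(w * f) / np.sum(w)))
        sigs.append(float(1.0 / np.sqrt(np.sum(w))))
    refl = ReflectionSet(np.array(hkl), np.array(fo2s), np.array(sigs))
    if cell is not None:
        refl.attach_cell(cell)
    return refl


def write_hkl(reflections: ReflectionSet) -> str:
    lines = [
        f"{h:4d}{k:4d}{l:4d}{fo2:8.2f}{sig:8.2f}"
        for (h, k, l), fo2, sig in zip(
            reflections.hkl, reflections.fo2, reflections.sigma
        )
    ]
    lines.append(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}")
    return "\n".join(lines) + "\n"


def write_fcf(
    reflections: ReflectionSet, fc: np.ndarray
) -> str:
    """Phased reflection listing: h k l Fo^2 sigma Fc^2 phase(deg)."""
    out = ["#  h   k   l      Fo^2     sigma      Fc^2     phase"]
    phases = np.degrees(np.angle(fc))
    fc2 = np.abs(fc) ** 2
    for (h, k, l), fo2, sig, f2, ph in zip(
        reflections.hkl, reflections.fo2, reflections.sigma, fc2, phases
    ):
        out.append(f"{h:4d}{k:4d}{l:4d}{fo2:10.3f}{sig:10.3f}{f2:10.3f}{ph:10.2f}")
    return "\n".join(out) + "\n"
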