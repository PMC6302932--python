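"""Packaged element data: analytic form-factor coefficients and covalent radii.

Form-factor coefficients are the standard four-Gaussian-plus-constant fits
tabulated in International Tables for Crystallography Vol. C (Table 6.1.1.4)
for neutral atoms.
"""

from __future__ import annotations

from .model import GaussianCoefficients

__all__ = ["FORM_FACTORS", "COVALENT_RADII", "ATOMIC_NUMBERS", "form_factor_coefficients"]

# element -> (a1..a4, b1..b4, c)
_ITC_TABLE: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": (
        (0.489918, 0.262003, 0.196767, 0.049879),
        (20.6593, 7.74039, 49.5519, 2.20159),
        0.001305,
    ),
    "C": (
        (2.31000, 1.02000, 1.58860, 0.865000),
        (20.8439, 10.2075, 0.568700, 51.6512),
        0.215600,
    ),
    "N": (
        (12.2126, 3.13220, 2.01250, 1.16630),
        (0.005700, 9.89330, 28.9975, 0.582600),
        -11.529,
    ),
    "O": (
        (3.04850, 2.28680, 1.54630, 0.867000),
        (13.2771, 5.70110, 0.323900, 32.9089),
        0.250800,
    ),
    "F": (
        (3.53920, 2.64120, 1.51700, 1.02430),
        (10.2825, 4.29440, 0.261500, 26.1476),
        0.277600,
    ),
    "P": (
        (6.43450, 4.17910, 1.78000, 1.49080),
        (1.90670, 27.1570, 0.526000, 68.1645),
        1.11490,
    ),
    "S": (
        (6.90530, 5.20340, 1.43790, 1.58630),
        (1.46790, 22.2151, 0.253600, 56.1720),
        0.866900,
    ),
    "Cl": (
        (11.4604, 7.19640, 6.25560, 1.64550),
        (0.010400, 1.16620, 18.5194, 47.7784),
        -9.5574,
    ),
    "Fe": (
        (11.7695, 7.35730, 3.52220, 2.30450),
        (4.76110, 0.307200, 15.3535, 76.8805),
        1.03690,
    ),
    "Zn": (
        (14.0743, 7.03180, 5.16520, 2.41000),
        (3.26550, 0.233300, 10.3163, 58.7097),
        1.30410,
    ),
    "Br": (
        (17.1789, 5.23580, 5.63770, 3.98510),
        (2.17230, 16.5796, 0.260900, 41.4328),
        2.95570,
    ),
}

FORM_FACTORS: dict[str, GaussianCoefficients] = {
    el: GaussianCoefficients(a=a, b=b, c=c) for el, (a, b, c) in _ITC_TABLE.items()
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16, "Cl": 17,
    "Fe": 26, "Zn": 30, "Br": 35,
}

# Covalent radii in angstrom (Cordero et al. consensus values).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Fe": 1.32, "Zn": 1.22, "Br": 1.20,
}


def form_factor_coefficients(element: str) -> GaussianCoefficients:
    """Look up tabulated coefficients, case-normalizing the symbol."""
    symbol = element.capitalize()
    try:
        return FORM_FACTORS[symbol]
    except KeyError:
        raise KeyError(
            f"no tabulated form-factor coefficients for element {element!r}; "
            f"available: {sorted(FORM_FACTORS)}"
        ) from None
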