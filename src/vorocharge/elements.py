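"""Element data: symbols, covalent and van der Waals radii, default core charges.

All radii are in picometres. Covalent radii follow the Cordero et al.
consensus single-bond values; van der Waals radii follow Bondi with
Alvarez values filling the gaps. Core charges default to the valence
electron count of the neutral atom, which is the right convention for
pseudopotential (valence-only) densities; full nuclear charges can be
substituted for all-electron densities via a user table.
"""

from __future__ import annotations

# fmt: off
ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "Kr": 36,
    "I": 53, "Xe": 54,
}

SYMBOLS: dict[int, str] = {z: s for s, z in ATOMIC_NUMBERS.items()}

#: Covalent radii / pm (Cordero-type consensus values).
COVALENT_RADII: dict[str, float] = {
    "H": 31.0, "He": 28.0, "Li": 128.0, "Be": 96.0, "B": 84.0, "C": 76.0,
    "N": 71.0, "O": 66.0, "F": 57.0, "Ne": 58.0, "Na": 166.0, "Mg": 141.0,
    "Al": 121.0, "Si": 111.0, "P": 107.0, "S": 105.0, "Cl": 102.0,
    "Ar": 106.0, "K": 203.0, "Ca": 176.0, "Br": 120.0, "Kr": 116.0,
    "I": 139.0, "Xe": 140.0,
}

#: van der Waals radii / pm (Bondi; Alvarez where Bondi gives none).
VDW_RADII: dict[str, float] = {
    "H": 120.0, "He": 140.0, "Li": 182.0, "Be": 153.0, "B": 192.0,
    "C": 170.0, "N": 155.0, "O": 152.0, "F": 147.0, "Ne": 154.0,
    "Na": 227.0, "Mg": 173.0, "Al": 184.0, "Si": 210.0, "P": 180.0,
    "S": 180.0, "Cl": 175.0, "Ar": 188.0, "K": 275.0, "Ca": 231.0,
    "Br": 185.0, "Kr": 202.0, "I": 198.0, "Xe": 216.0,
}

#: Default core charges / e: valence electron counts (pseudopotential densities).
DEFAULT_CORE_CHARGES: dict[str, float] = {
    "H": 1.0, "He": 2.0, "Li": 1.0, "Be": 2.0, "B": 3.0, "C": 4.0,
    "N": 5.0, "O": 6.0, "F": 7.0, "Ne": 8.0, "Na": 1.0, "Mg": 2.0,
    "Al": 3.0, "Si": 4.0, "P": 5.0, "S": 6.0, "Cl": 7.0, "Ar": 8.0,
    "K": 1.0, "Ca": 2.0, "Br": 7.0, "Kr": 8.0, "I": 7.0, "Xe": 8.0,
}
# fmt: on

#: Bohr radius in pm; CUBE files are in atomic units.
BOHR_PM = 52.9177210903


class UnknownElementError(KeyError):
    """Raised when an element symbol is missing from a lookup table."""


def covalent_radius(symbol: str) -> float:
    try:
        return COVALENT_RADII[symbol]
    except KeyError:
        raise UnknownElementError(f"no covalent radius for element {symbol!r}") from None


def vdw_radius(symbol: str) -> float:
    try:
        return VDW_RADII[symbol]
    except KeyError:
        raise UnknownElementError(f"no van der Waals radius for element {symbol!r}") from None


def default_core_charge(symbol: str) -> float:
    try:
        return DEFAULT_CORE_CHARGES[symbol]
    except KeyError:
        raise UnknownElementError(f"no core charge for element {symbol!r}") from None
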