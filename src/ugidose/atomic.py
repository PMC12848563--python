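"""Standard atomic weights and atomic numbers for the elements handled by the
attenuation database.

Weights follow the CIAAW conventional (abridged) values; for elements quoted
as an interval the conventional single value is used.  Units: g/mol.
"""

from __future__ import annotations

ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Fe": 26, "Cu": 29,
    "Zn": 30, "I": 53, "Ba": 56, "W": 74, "Pb": 82,
}

ATOMIC_WEIGHT: dict[str, float] = {
    "H": 1.008,
    "He": 4.0026,
    "Li": 6.94,
    "Be": 9.0122,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403,
    "Ne": 20.1797,
    "Na": 22.98977,
    "Mg": 24.305,
    "Al": 26.98154,
    "Si": 28.085,
    "P": 30.97376,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.95,
    "K": 39.0983,
    "Ca": 40.078,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "I": 126.90447,
    "Ba": 137.327,
    "W": 183.84,
    "Pb": 207.2,
}


def atomic_weight(symbol: str) -> float:
    """Atomic weight of an element symbol, g/mol."""
    try:
        return ATOMIC_WEIGHT[symbol]
    except KeyError:
        raise KeyError(f"element {symbol!r} is not in the atomic-weight table") from None


def atomic_number(symbol: str) -> int:
    try:
        return ATOMIC_NUMBER[symbol]
    except KeyError:
        raise KeyError(f"element {symbol!r} is not in the atomic-number table") from None
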