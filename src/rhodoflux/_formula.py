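"""Elemental-formula parsing and degree-of-reduction arithmetic.

The degree of reduction gamma of a compound is the number of available
electrons per mole under the standard half-reaction reference states
(CO2 for C, H2O for O/H, NH3 for N, SO4^2- for S, PO4^3- for P):

    gamma = 4*C + 1*H - 2*O - 3*N + 6*S + 5*P - charge

so e.g. succinate C4H6O4 gives 14 e-/mol, H2 gives 2 e-/mol and fully
oxidized species (CO2, sulfate, phosphate) give 0.  The COD equivalence
used throughout is 8 gCOD per electron-mole.
"""

from __future__ import annotations

import re

# electrons contributed per atom, half-reaction convention
_ELECTRONS = {
    "C": 4, "H": 1, "O": -2, "N": -3, "S": 6, "P": 5,
    # redox-inert in the convention used here
    "Fe": 0, "Mg": 0, "Ca": 0, "K": 0, "Na": 0, "Cl": -1,
}

_ATOMIC_MASS = {
    "C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "S": 32.06,
    "P": 30.974, "Fe": 55.845, "Mg": 24.305, "Ca": 40.078, "K": 39.098,
    "Na": 22.990, "Cl": 35.45,
}

GRAMS_COD_PER_EMOL = 8.0

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``C4H6O4`` style formulas into an element -> count map."""
    if formula is None:
        raise ValueError("no formula given")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparsable formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"unparsable formula {formula!r}")
    return counts


def degree_of_reduction(formula: str, charge: int = 0) -> float:
    """Available electrons per mole of the compound (may be negative)."""
    total = 0.0
    for element, n in parse_formula(formula).items():
        if element not in _ELECTRONS:
            raise ValueError(f"element {element!r} has no half-reaction convention")
        total += _ELECTRONS[element] * n
    return total - charge


def molecular_weight(formula: str) -> float:
    total = 0.0
    for element, n in parse_formula(formula).items():
        if element not in _ATOMIC_MASS:
            raise ValueError(f"no atomic mass for element {element!r}")
        total += _ATOMIC_MASS[element] * n
    return total


def element_count(formula: str, element: str) -> int:
    """Number of atoms of ``element`` in ``formula`` (0 if absent)."""
    return parse_formula(formula).get(element, 0)
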