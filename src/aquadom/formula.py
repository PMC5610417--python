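"""Elemental formulae and exact-mass arithmetic.

A :class:`Formula` holds integer element counts for a *neutral* molecule.
Chlorine only ever appears through adduct bookkeeping downstream; assigned
neutral formulae carry ``Cl == 0``.
"""

from __future__ import annotations

import re
from typing import NamedTuple

from .isotope_data import MONO_MASS, NOMINAL_MASS

ELEMENT_ORDER = ("C", "H", "O", "N", "S", "P", "Cl")

# Hill order: C, H, then remaining elements alphabetically.
_HILL_ORDER = ("C", "H", "Cl", "N", "O", "P", "S")

_TOKEN = re.compile(r"(Cl|C|H|O|N|S|P)(\d*)")


class Formula(NamedTuple):
    """Integer element counts of a neutral molecule."""

    C: int = 0
    H: int = 0
    O: int = 0
    N: int = 0
    S: int = 0
    P: int = 0
    Cl: int = 0

    def __add__(self, other: "Formula") -> "Formula":  # type: ignore[override]
        return Formula(*(a + b for a, b in zip(self, other)))

    def __sub__(self, other: "Formula") -> "Formula":
        return Formula(*(a - b for a, b in zip(self, other)))

    def scaled(self, k: int) -> "Formula":
        return Formula(*(k * a for a in self))

    @property
    def is_valid(self) -> bool:
        return all(a >= 0 for a in self)

    def hill(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        parts = []
        for el in _HILL_ORDER:
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts) or ""

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(s: str) -> Formula:
    """Parse a Hill-order formula string such as ``"C6H12O6"``."""
    counts = dict.fromkeys(ELEMENT_ORDER, 0)
    pos = 0
    for m in _TOKEN.finditer(s):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {s!r}")
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(s):
        raise ValueError(f"cannot parse formula {s!r}")
    return Formula(**counts)


# CH2 / CO2 elongation units used for homologous series.
CH2 = Formula(C=1, H=2)
CO2 = Formula(C=1, O=2)


def monoisotopic_mass(f: Formula) -> float:
    """Neutral monoisotopic mass in Da (sum of principal-isotope masses)."""
    return sum(n * MONO_MASS[el] for el, n in zip(Formula._fields, f))


def nominal_mass(f: Formula) -> int:
    """Integer nominal mass (sum of principal mass numbers)."""
    return sum(n * NOMINAL_MASS[el] for el, n in zip(Formula._fields, f))


def double_bond_equivalents(f: Formula, p_valence: int = 3) -> float:
    """Double bond equivalents of the neutral molecule.

    Uses the trivalent-phosphorus convention by default,
    ``DBE = 1 + C - H/2 + N/2 + P/2``; with ``p_valence=5`` phosphorus
    contributes 3/2 per atom instead.
    """
    p_coef = (p_valence - 2) / 2.0
    return 1.0 + f.C - f.H / 2.0 + f.N / 2.0 + p_coef * f.P


def heteroatom_class(f: Formula) -> str:
    """Compound class label (CHO, CHON..CHON4, CHOS/CHOS2, CHOP/CHOP2).

    Formulae satisfying the assignment constraints carry at most one
    heteroelement kind; if several are present the label follows the
    first of N, S, P.
    """
    if f.N > 0:
        return "CHON" if f.N == 1 else f"CHON{f.N}"
    if f.S > 0:
        return "CHOS" if f.S == 1 else f"CHOS{f.S}"
    if f.P > 0:
        return "CHOP" if f.P == 1 else f"CHOP{f.P}"
    return "CHO"
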