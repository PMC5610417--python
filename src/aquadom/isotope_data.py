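"""Embedded isotope masses and natural abundances.

Values are the standard atomic-physics reference constants (monoisotopic
masses in Da, natural abundances as mole fractions). They are embedded
rather than fetched so that every mass computation in the package is
reproducible offline.
"""

from __future__ import annotations

ELECTRON_MASS = 0.000548579909  # Da

#: Per element: ordered list of (exact mass, natural abundance), principal
#: (most abundant / lightest) isotope first, masses strictly increasing.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "O": [
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ],
    "N": [(14.00307400443, 0.99636), (15.00010889888, 0.00364)],
    "S": [
        (31.9720711744, 0.9499),
        (32.9714589098, 0.0075),
        (33.967867004, 0.0425),
        (35.96708071, 0.0001),
    ],
    "P": [(30.97376199842, 1.0)],
    "Cl": [(34.968852682, 0.7576), (36.965902602, 0.2424)],
}

#: Principal-isotope (monoisotopic) mass per element.
MONO_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

#: Integer nominal mass per element (mass number of the principal isotope).
NOMINAL_MASS: dict[str, int] = {el: round(iso[0][0]) for el, iso in ISOTOPES.items()}

PROTON_MASS = MONO_MASS["H"] - ELECTRON_MASS
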