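"""Independent reference implementations used only by the tests.

These deliberately avoid the package's optimized code paths: enumeration
is a plain masked scan over the full element lattice with no solved-for
hydrogen, and the isotopologue oracle builds per-element distributions by
repeated convolution of the single-atom distribution.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from aquadom.engine import EnumerationLimits, passes_constraints
from aquadom.formula import Formula, monoisotopic_mass
from aquadom.isotope_data import ISOTOPES, MONO_MASS


@lru_cache(maxsize=2)
def _full_lattice(limits: EnumerationLimits):
    """Masses and counts for every (C,H,O,N,S,P) tuple within the element
    limits (heteroatoms restricted to one kind, as the co-occurrence rule
    discards the rest anyway)."""
    classes = [(0, 0, 0)]
    classes += [(n, 0, 0) for n in range(1, limits.max_n + 1)]
    classes += [(0, s, 0) for s in range(1, limits.max_s + 1)]
    classes += [(0, 0, p) for p in range(1, limits.max_p + 1)]
    c = np.arange(1, limits.max_c + 1)
    h = np.arange(1, limits.max_h + 1)
    o = np.arange(1, limits.max_o + 1)
    cc, hh, oo = np.meshgrid(c, h, o, indexing="ij")
    cc, hh, oo = cc.ravel(), hh.ravel(), oo.ravel()
    base = 12.0 * cc + MONO_MASS["H"] * hh + MONO_MASS["O"] * oo
    out = []
    for n, s, p in classes:
        het = n * MONO_MASS["N"] + s * MONO_MASS["S"] + p * MONO_MASS["P"]
        out.append((base + het, cc, hh, oo, n, s, p))
    return out

def brute_force_candidates(
    target: float, limits: EnumerationLimits
) -> list[Formula]:
    """Exhaustive enumeration by masked scan over the full lattice."""
    tol = limits.tol_ppm * 1e-6 * target
    hits: list[tuple[float, Formula]] = []
    for masses, cc, hh, oo, n, s, p in _full_lattice(limits):
        sel = np.nonzero(np.abs(masses - target) <= tol)[0]
        for i in sel:
            f = Formula(C=int(cc[i]), H=int(hh[i]), O=int(oo[i]), N=n, S=s, P=p)
            if passes_constraints(f, limits) is None:
                hits.append((abs(masses[i] - target) / target, f))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [f for _, f in hits]


def convolved_isotope_distribution(
    counts: dict[str, int], digits: int = 6
) -> dict[float, float]:
    """Absolute isotopologue distribution (mass shift -> probability) by
    per-element convolution of single-atom distributions."""
    dist = {0.0: 1.0}
    for el, n in counts.items():
        isos = ISOTOPES[el]
        single = {round(m - isos[0][0], digits): a for m, a in isos}
        el_dist = {0.0: 1.0}
        for _ in range(n):
            nxt: dict[float, float] = {}
            for s1, p1 in el_dist.items():
                for s2, p2 in single.items():
                    key = round(s1 + s2, digits)
                    nxt[key] = nxt.get(key, 0.0) + p1 * p2
            el_dist = nxt
        nxt_total: dict[float, float] = {}
        for s1, p1 in dist.items():
            for s2, p2 in el_dist.items():
                key = round(s1 + s2, digits)
                nxt_total[key] = nxt_total.get(key, 0.0) + p1 * p2
        dist = nxt_total
    return dist
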