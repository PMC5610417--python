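"""Theoretical isotopologue patterns and isotope-based confirmation.

Candidate assignments are confirmed by checking that the spectrum contains
isotopologue daughter peaks at the expected mass shifts (within a ppm
tolerance) and expected intensity ratios to the monoisotopic parent
(within a relative window). One matching daughter confirms a formula; two
are required for chloride adducts, whose abundant secondary chlorine
isotope produces prominent daughters beyond the 13C series.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .characterization import STRICT_GROUPS, classify_group
from .engine import Assignment, CHLORIDE_ADDUCT, Spectrum, ion_mz
from .formula import Formula, monoisotopic_mass
from .isotope_data import ISOTOPES

#: Elements whose heavy isotopes are considered (all except P, which is
#: monoisotopic in nature anyway).
PATTERN_ELEMENTS = ("C", "H", "O", "N", "S", "Cl")


@dataclass(frozen=True)
class IsotopologuePattern:
    """Daughter peaks as (mass shift from parent, intensity ratio to
    parent), sorted by expected ratio descending."""

    shifts: tuple[float, ...]
    ratios: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.shifts)


def _element_substitutions(n_atoms: int, isotopes, max_subs: Optional[int]):
    """Yield (mass shift, probability ratio to all-principal) for every
    heavy-substitution pattern of one element with ``n_atoms`` atoms.

    The ratio for substitution counts (k1, k2, ...) over heavy isotopes
    with abundances a1, a2, ... relative to the principal a0 is the
    multinomial coefficient times prod (ai/a0)^ki.
    """
    heavy = isotopes[1:]
    m0 = isotopes[0][0]
    a0 = isotopes[0][1]
    n_heavy = len(heavy)
    if n_heavy == 0 or n_atoms == 0:
        yield 0.0, 1.0, 0
        return
    cap = n_atoms if max_subs is None else min(max_subs, n_atoms)
    for total in range(cap + 1):
        for ks in _compositions(total, n_heavy):
            ratio = 1.0
            # multinomial coefficient C(n; n-total, k1, ..) via falling factorial
            remaining = n_atoms
            coeff = 1.0
            for k in ks:
                coeff *= math.comb(remaining, k)
                remaining -= k
            ratio = coeff
            shift = 0.0
            for k, (m, a) in zip(ks, heavy):
                ratio *= (a / a0) ** k
                shift += k * (m - m0)
            yield shift, ratio, total


def _compositions(total: int, parts: int):
    """All tuples of ``parts`` non-negative ints summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


@lru_cache(maxsize=4096)
def _pattern_cached(
    counts: tuple[int, ...],
    n_max: int,
    max_subs: Optional[int],
    resolution: float,
    min_ratio: float,
) -> IsotopologuePattern:
    per_element = []
    for el, n in zip(PATTERN_ELEMENTS, counts):
        subs = list(_element_substitutions(n, ISOTOPES[el], max_subs))
        per_element.append(subs)

    raw: list[tuple[float, float]] = []
    for combo in itertools.product(*per_element):
        total = sum(c[2] for c in combo)
        if max_subs is not None and total > max_subs:
            continue
        if total == 0:
            continue
        ratio = 1.0
        shift = 0.0
        for s, r, _ in combo:
            ratio *= r
            shift += s
        if ratio >= min_ratio:
            raw.append((shift, ratio))

    # merge fine structure closer than the instrument resolution
    raw.sort()
    merged: list[tuple[float, float]] = []
    for shift, ratio in raw:
        if merged and shift - merged[-1][0] < resolution:
            s0, r0 = merged[-1]
            tot = r0 + ratio
            merged[-1] = ((s0 * r0 + shift * ratio) / tot, tot)
        else:
            merged.append((shift, ratio))
    merged.sort(key=lambda t: -t[1])
    merged = merged[:n_max]
    return IsotopologuePattern(
        shifts=tuple(s for s, _ in merged), ratios=tuple(r for _, r in merged)
    )


def theoretical_isotopologues(
    f: Formula,
    species: str = "deprotonated",
    n_max: int = 10,
    max_subs: Optional[int] = 3,
    resolution: float = 0.0005,
    min_ratio: float = 1e-6,
) -> IsotopologuePattern:
    """Expected isotopologue daughters of an assigned formula's ion.

    Single- and multi-substitution isotopologues of C, H, O, N, S and the
    adduct chlorine (P excluded) are generated from the embedded isotope
    table by multinomial expansion; intensity ratios are relative to the
    monoisotopic parent. Fine-structure peaks closer than ``resolution``
    Da are merged by abundance-weighted mass; the ``n_max`` most intense
    daughters are returned. ``max_subs=None`` enumerates the untruncated
    distribution.
    """
    cl = 1 if species == CHLORIDE_ADDUCT else 0
    counts = (f.C, f.H, f.O, f.N, f.S, cl)
    return _pattern_cached(counts, n_max, max_subs, resolution, min_ratio)


def isotopologue_probability_sum(f: Formula, species: str = "deprotonated") -> float:
    """Sum of all isotopologue probabilities (monoisotopic included) of
    the untruncated multinomial expansion, on the absolute scale. Equals
    1 for any formula when the abundance table is complete."""
    cl = 1 if species == CHLORIDE_ADDUCT else 0
    counts = (f.C, f.H, f.O, f.N, f.S, cl)
    total = 0.0
    pattern = _pattern_cached(counts, n_max=10**9, max_subs=None,
                              resolution=0.0, min_ratio=0.0)
    mono_prob = 1.0
    for el, n in zip(PATTERN_ELEMENTS, counts):
        mono_prob *= ISOTOPES[el][0][1] ** n
    total = mono_prob * (1.0 + sum(pattern.ratios))
    return total


@dataclass
class IsotopeEvidence:
    """Outcome of matching expected daughters against observed peaks."""

    matched: list[tuple[float, float, float]] = field(default_factory=list)
    confirmed: bool = False
    strict_mode: bool = False

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def verify(
    a: Assignment,
    s: Spectrum,
    tol_ppm: float = 0.6,
    ratio_window: float = 0.4,
    n_max: int = 10,
    strict_mode: bool = False,
) -> IsotopeEvidence:
    """Match the assignment's expected daughters against the spectrum.

    A daughter matches when a peak lies within ``tol_ppm`` of the
    candidate ion's theoretical m/z plus the expected shift AND its
    intensity ratio to the parent is within ``ratio_window`` (relative)
    of the expected ratio. Anchoring on the theoretical parent position
    keeps the daughter check independent of the parent's own mass error.
    The nearest in-tolerance peak is taken; ties break to the higher
    intensity. Confirmation requires one matched daughter, or two for
    chloride adducts.
    """
    pattern = theoretical_isotopologues(a.formula, a.species, n_max=n_max)
    ev = IsotopeEvidence(strict_mode=strict_mode)
    parent_mz = ion_mz(monoisotopic_mass(a.formula), a.species)
    parent_int = a.intensity
    for shift, exp_ratio in zip(pattern.shifts, pattern.ratios):
        target = parent_mz + shift
        tol_da = tol_ppm * 1e-6 * target
        lo = np.searchsorted(s.mz, target - tol_da, side="left")
        hi = np.searchsorted(s.mz, target + tol_da, side="right")
        best = None
        for j in range(lo, hi):
            if j == a.peak_index:
                continue
            dist = abs(s.mz[j] - target)
            key = (dist, -s.intensity[j])
            if best is None or key < best[0]:
                best = (key, j)
        if best is None:
            continue
        j = best[1]
        obs_ratio = s.intensity[j] / parent_int
        deviation = obs_ratio / exp_ratio - 1.0
        if abs(deviation) <= ratio_window + 1e-12:
            ev.matched.append((shift, float(s.mz[j] - parent_mz), float(deviation)))
    required = 2 if a.species == CHLORIDE_ADDUCT else 1
    ev.confirmed = ev.n_matched >= required
    return ev


def needs_strict(f: Formula) -> bool:
    """Stricter limits apply to heteroatom formulae (N, S, P) and to
    condensed polyaromatics, saturated fatty acids and carbohydrates."""
    if f.N > 0 or f.S > 0 or f.P > 0:
        return True
    return classify_group(f) in STRICT_GROUPS


def verify_strict(a: Assignment, s: Spectrum, n_max: int = 10) -> IsotopeEvidence:
    """Confirmation with halved tolerance (0.3 ppm) and halved ratio
    window (±20%)."""
    return verify(a, s, tol_ppm=0.3, ratio_window=0.2, n_max=n_max, strict_mode=True)


def verify_auto(
    a: Assignment,
    s: Spectrum,
    tol_ppm: float = 0.6,
    ratio_window: float = 0.4,
    n_max: int = 10,
) -> IsotopeEvidence:
    """Route to strict or standard verification based on the candidate
    formula itself (heteroatoms or strict molecular groups)."""
    if needs_strict(a.formula):
        return verify(
            a, s, tol_ppm=tol_ppm / 2, ratio_window=ratio_window / 2,
            n_max=n_max, strict_mode=True,
        )
    return verify(a, s, tol_ppm=tol_ppm, ratio_window=ratio_window, n_max=n_max)
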