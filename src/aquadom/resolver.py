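"""Resolution of multiple candidate assignments per peak.

When a peak carries several isotope-checked candidates the winner is
chosen by a fixed preference cascade: (i) compound classes that are
extremely abundant in environmental samples (CHO, CHON, CHON2, CHOS)
outrank all others; (ii) better isotope confirmation — more matched
daughter peaks, then confirmation across more samples; (iii) longer
homologous series built on CH2 (aliphatic elongation) or CO2 (acid
elongation); remaining ties fall to the smaller absolute mass error and
finally lexicographic formula order, so resolution is fully
deterministic. Intensities of a formula seen both deprotonated and as a
chloride adduct are summed afterwards.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .engine import Assignment
from .formula import CH2, CO2, Formula, heteroatom_class

PREFERRED_CLASSES = frozenset({"CHO", "CHON", "CHON2", "CHOS"})


def homologous_series_length(f: Formula, pool: set[Formula], delta: Formula) -> int:
    """Length of the maximal contiguous chain {f + k*delta} inside the
    pool that contains f. Gaps break the chain."""
    if f not in pool:
        raise ValueError("formula not in pool")
    length = 1
    g = f + delta
    while g in pool:
        length += 1
        g = g + delta
    g = f - delta
    while g.is_valid and g in pool:
        length += 1
        g = g - delta
    return length


@dataclass
class ResolutionContext:
    """Study-wide evidence tallies used by the preference cascade.

    ``pool`` is the union of candidate formulae across all samples'
    assignments; ``samples_confirmed`` counts, per formula, the samples
    in which it achieved isotope confirmation.
    """

    pool: set[Formula] = field(default_factory=set)
    samples_confirmed: dict[Formula, int] = field(default_factory=dict)
    _series_cache: dict[Formula, int] = field(default_factory=dict)

    @classmethod
    def from_assignments(cls, assignments: Iterable[Assignment]) -> "ResolutionContext":
        pool: set[Formula] = set()
        confirmed_in: dict[Formula, set[str]] = defaultdict(set)
        for a in assignments:
            pool.add(a.formula)
            if a.confirmed:
                confirmed_in[a.formula].add(a.sample_id)
        return cls(
            pool=pool,
            samples_confirmed={f: len(s) for f, s in confirmed_in.items()},
        )

    def series_length(self, f: Formula) -> int:
        """max(CH2-series, CO2-series) length of f within the pool."""
        if f not in self._series_cache:
            self._series_cache[f] = max(
                homologous_series_length(f, self.pool, CH2),
                homologous_series_length(f, self.pool, CO2),
            )
        return self._series_cache[f]


def resolve(candidates: Sequence[Assignment], ctx: ResolutionContext) -> Assignment:
    """Collapse the candidates for one peak to a single assignment."""
    if not candidates:
        raise ValueError("no candidates to resolve")
    if len(candidates) == 1:
        return candidates[0]

    def key(a: Assignment):
        return (
            0 if heteroatom_class(a.formula) in PREFERRED_CLASSES else 1,
            -a.n_daughters,
            -ctx.samples_confirmed.get(a.formula, 0),
            -ctx.series_length(a.formula),
            abs(a.error_ppm),
            a.formula.hill(),
            a.species,
        )

    return min(candidates, key=key)


def resolve_spectrum(
    assignments: Sequence[Assignment], ctx: ResolutionContext
) -> list[Assignment]:
    """Resolve every peak of one sample to at most one assignment."""
    by_peak: dict[int, list[Assignment]] = defaultdict(list)
    for a in assignments:
        by_peak[a.peak_index].append(a)
    return [resolve(cands, ctx) for _, cands in sorted(by_peak.items())]


def merge_species(resolved: Sequence[Assignment]) -> pd.DataFrame:
    """Per-formula intensity table for one sample.

    Intensities of a formula found deprotonated and as a chloride adduct
    are summed; a formula confirmed under either species counts as
    confirmed. Two peaks resolving to the same (formula, species) pair
    indicate an upstream duplicate and raise.
    """
    seen: set[tuple[Formula, str]] = set()
    acc: dict[Formula, dict] = {}
    for a in resolved:
        pair = (a.formula, a.species)
        if pair in seen:
            raise ValueError(
                f"duplicate resolved assignment for {a.formula.hill()} ({a.species})"
            )
        seen.add(pair)
        rec = acc.setdefault(
            a.formula,
            {"intensity": 0.0, "confirmed": False, "n_daughters": 0, "max_sn": 0.0},
        )
        rec["intensity"] += a.intensity
        rec["confirmed"] = rec["confirmed"] or a.confirmed
        rec["n_daughters"] = max(rec["n_daughters"], a.n_daughters)
        rec["max_sn"] = max(rec["max_sn"], a.sn)
    rows = [
        {
            "formula": f.hill(),
            "intensity": rec["intensity"],
            "confirmed": rec["confirmed"],
            "n_daughters": rec["n_daughters"],
            "max_sn": rec["max_sn"],
        }
        for f, rec in acc.items()
    ]
    return pd.DataFrame(
        rows, columns=["formula", "intensity", "confirmed", "n_daughters", "max_sn"]
    ).sort_values("formula").reset_index(drop=True)
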