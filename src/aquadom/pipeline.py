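"""End-to-end chain: assign -> verify -> resolve -> assemble.

Ties the formula engine, the isotope verifier, the assignment resolver
and the dataset assembly together into the study-level processing used by
the analysis drivers and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assembly import FilterLog, FormulaMatrix, assemble
from .engine import Assignment, DEFAULT_LIMITS, EnumerationLimits, Spectrum, assign_peaks
from .formula import Formula
from .resolver import ResolutionContext, merge_species, resolve_spectrum
from .verifier import theoretical_isotopologues, verify_auto


@dataclass
class StudyResult:
    matrix: FormulaMatrix
    log: FilterLog
    tables: dict[str, pd.DataFrame]
    blank_tables: dict[str, pd.DataFrame]


def assignments_for_spectrum(
    s: Spectrum,
    limits: EnumerationLimits = DEFAULT_LIMITS,
    tol_ppm: float = 0.6,
    ratio_window: float = 0.4,
) -> list[Assignment]:
    """Candidate assignments for one spectrum, with isotope evidence
    attached (strict limits auto-selected per candidate formula)."""
    assignments = assign_peaks(s, limits)
    for a in assignments:
        ev = verify_auto(a, s, tol_ppm=tol_ppm, ratio_window=ratio_window)
        a.n_daughters = ev.n_matched
        a.confirmed = ev.confirmed
        a.strict_mode = ev.strict_mode
    return assignments


def drop_isotopologue_peaks(
    resolved: list[Assignment], exclusion_ppm: float = 2.0, n_max: int = 10
) -> list[Assignment]:
    """Remove resolved assignments sitting on isotopologue peaks.

    A peak lying within ``exclusion_ppm`` of an expected daughter
    position of a more intense resolved assignment in the same spectrum
    is an isotopologue, not a monoisotopic ion; its intensity serves
    verification and it is not reported as a molecular formula. Peaks are
    visited by descending intensity (monoisotopic parents outshine their
    daughters), so exclusion is deterministic.
    """
    order = sorted(resolved, key=lambda a: (-a.intensity, a.mz))
    windows: list[tuple[float, float]] = []
    kept: list[Assignment] = []
    for a in order:
        if any(lo <= a.mz <= hi for lo, hi in windows):
            continue
        kept.append(a)
        pattern = theoretical_isotopologues(a.formula, a.species, n_max=n_max)
        for shift in pattern.shifts:
            target = a.mz + shift
            tol = exclusion_ppm * 1e-6 * target
            windows.append((target - tol, target + tol))
    kept.sort(key=lambda a: a.peak_index)
    return kept


def process_study(
    spectra: Sequence[Spectrum],
    limits: EnumerationLimits = DEFAULT_LIMITS,
    sn_blank_threshold: float = 5.0,
    isotopologue_exclusion_ppm: float = 2.0,
) -> StudyResult:
    """Run the full molecular-formula pipeline over a replicate study.

    All spectra (samples and blanks) are assigned and isotope-checked;
    multiple assignments per peak are resolved with study-wide evidence;
    peaks identified as isotopologues of stronger assignments are
    excluded; per-sample formula tables are aligned and passed through
    the confirmation, blank and replicate filters.
    """
    per_spec: dict[str, list[Assignment]] = {}
    for s in spectra:
        per_spec[s.sample_id] = assignments_for_spectrum(s, limits)

    ctx = ResolutionContext.from_assignments(
        a for assigns in per_spec.values() for a in assigns
    )

    tables: dict[str, pd.DataFrame] = {}
    blank_tables: dict[str, pd.DataFrame] = {}
    meta_rows = {}
    for s in spectra:
        resolved = resolve_spectrum(per_spec[s.sample_id], ctx)
        if isotopologue_exclusion_ppm > 0:
            resolved = drop_isotopologue_peaks(resolved, isotopologue_exclusion_ppm)
        table = merge_species(resolved)
        if s.is_blank:
            blank_tables[s.sample_id] = table
        else:
            tables[s.sample_id] = table
            meta_rows[s.sample_id] = {
                "source": s.source,
                "day": s.day,
                "replicate_set": s.replicate_set,
            }

    sample_meta = pd.DataFrame(meta_rows).T
    matrix, log = assemble(tables, blank_tables, sample_meta, sn_blank_threshold)
    return StudyResult(matrix=matrix, log=log, tables=tables, blank_tables=blank_tables)


def recovery(matrix: FormulaMatrix, planted: Iterable[Formula]) -> float:
    """Fraction of planted formulae present in the final matrix."""
    rows = set(map(str, matrix.formulae))
    planted = [f.hill() for f in planted]
    if not planted:
        raise ValueError("no planted formulae")
    return sum(1 for f in planted if f in rows) / len(planted)
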