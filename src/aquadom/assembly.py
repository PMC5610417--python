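"""Cross-sample assembly of formula tables and the three dataset filters.

Per-sample formula/intensity tables are aligned into a formulae x samples
matrix on exact formulae. Three filters are applied in a fixed order:
(1) confirmation — formulae never isotope-confirmed in any sample are
dropped; (2) blank filter — formulae found at S/N > 5 in any blank are
contaminants and deleted everywhere; (3) replicate filter — a formula
present in exactly one member of a replicate set (same source and
incubation time) is zeroed in that set; single-member sets are exempt.
Columns are renormalized to relative intensities afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class FormulaMatrix:
    """Formulae x samples relative-intensity matrix with per-cell
    confirmation flags and per-sample metadata (source, time, replicate
    set, blank flag)."""

    intensities: pd.DataFrame
    confirmed: pd.DataFrame
    samples: pd.DataFrame  # index = sample ids; columns source, day, replicate_set

    def copy(self) -> "FormulaMatrix":
        return FormulaMatrix(
            self.intensities.copy(), self.confirmed.copy(), self.samples.copy()
        )

    @property
    def formulae(self) -> pd.Index:
        return self.intensities.index


def align(
    tables: Mapping[str, pd.DataFrame],
    sample_meta: pd.DataFrame | None = None,
) -> FormulaMatrix:
    """Align per-sample tables (columns formula, intensity, confirmed)
    into a matrix over the union of formulae, keeping only formulae that
    achieved isotope confirmation in at least one sample. Absences are
    zeros; columns are scaled to relative intensities."""
    if not tables:
        raise ValueError("no samples")
    inten = {}
    conf = {}
    for sid, t in tables.items():
        inten[sid] = t.set_index("formula")["intensity"].astype(float)
        conf[sid] = t.set_index("formula")["confirmed"].astype(bool)
    m = pd.DataFrame(inten).fillna(0.0).sort_index()
    c = pd.DataFrame(conf).sort_index().astype("boolean").fillna(False).astype(bool)
    keep = c.any(axis=1)
    m, c = m.loc[keep], c.loc[keep]
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {"source": "", "day": np.nan, "replicate_set": ""}, index=m.columns
        )
    else:
        sample_meta = sample_meta.loc[m.columns]
    fm = FormulaMatrix(m, c, sample_meta)
    return renormalize(fm)


def remove_blank_contaminants(
    m: FormulaMatrix,
    blank_tables: Mapping[str, pd.DataFrame],
    sn_threshold: float = 5.0,
) -> tuple[FormulaMatrix, list[str]]:
    """Delete every formula found at S/N above threshold in any blank.

    Blank tables carry a per-formula ``max_sn`` column (highest S/N of
    the peaks that produced the formula in that blank). Returns the
    filtered matrix and the list of removed formulae."""
    if not blank_tables:
        warnings.warn("no blank samples provided; blank filter is vacuous")
        return m.copy(), []
    contaminants: set[str] = set()
    for t in blank_tables.values():
        hits = t.loc[t["max_sn"] > sn_threshold, "formula"]
        contaminants.update(hits.tolist())
    removed = sorted(contaminants & set(m.formulae.astype(str)))
    out = m.copy()
    out.intensities = out.intensities.drop(index=removed)
    out.confirmed = out.confirmed.drop(index=removed)
    return renormalize(out), removed


def replicate_filter(m: FormulaMatrix) -> tuple[FormulaMatrix, int]:
    """Zero singlet formulae within each replicate set of size >= 2.

    A formula detected in exactly one member of a set is zeroed there;
    sets with a single member are exempt. Rows left all-zero are
    dropped. Returns the filtered matrix and the number of zeroed
    singlet occurrences."""
    out = m.copy()
    vals = out.intensities
    n_removed = 0
    for rep_set, cols in out.samples.groupby("replicate_set").groups.items():
        cols = list(cols)
        if len(cols) < 2:
            continue
        block = vals[cols]
        presence = (block > 0).sum(axis=1)
        singlets = presence == 1
        n_removed += int(singlets.sum())
        vals.loc[singlets, cols] = 0.0
    keep = vals.sum(axis=1) > 0
    out.intensities = vals.loc[keep]
    out.confirmed = out.confirmed.loc[keep]
    return renormalize(out), n_removed


def renormalize(m: FormulaMatrix) -> FormulaMatrix:
    """Rescale every column to relative intensities summing to one."""
    tot = m.intensities.sum(axis=0)
    if (tot <= 0).any():
        bad = tot.index[tot <= 0].tolist()
        raise ValueError(f"all-zero sample column(s) after filtering: {bad}")
    out = m.copy()
    out.intensities = m.intensities / tot
    return out


@dataclass
class FilterLog:
    n_input_formulae: int = 0
    n_unconfirmed_dropped: int = 0
    blank_contaminants: list[str] = field(default_factory=list)
    n_singlets_removed: int = 0
    n_final_formulae: int = 0


def assemble(
    tables: Mapping[str, pd.DataFrame],
    blank_tables: Mapping[str, pd.DataFrame],
    sample_meta: pd.DataFrame,
    sn_threshold: float = 5.0,
) -> tuple[FormulaMatrix, FilterLog]:
    """Run the full filter chain: confirmation -> blank -> replicate."""
    union = set()
    for t in tables.values():
        union.update(t["formula"].tolist())
    log = FilterLog(n_input_formulae=len(union))
    m = align(tables, sample_meta)
    log.n_unconfirmed_dropped = log.n_input_formulae - m.intensities.shape[0]
    m, removed = remove_blank_contaminants(m, blank_tables, sn_threshold)
    log.blank_contaminants = removed
    m, n_singlets = replicate_filter(m)
    log.n_singlets_removed = n_singlets
    log.n_final_formulae = m.intensities.shape[0]
    return m, log
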