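"""Constrained enumeration and assignment of molecular formulae.

Peaks from electrospray-negative ultrahigh-resolution spectra are tried as
singly charged deprotonated molecules ([M-H]-) and chloride adducts
([M+Cl]-). Candidate neutral formulae are enumerated exhaustively within
elemental limits and chemical plausibility rules, with the mass tolerance
applied on the neutral mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .formula import Formula, double_bond_equivalents, monoisotopic_mass, nominal_mass
from .isotope_data import ELECTRON_MASS, MONO_MASS

DEPROTONATED = "deprotonated"
CHLORIDE_ADDUCT = "chloride_adduct"
ION_SPECIES = (DEPROTONATED, CHLORIDE_ADDUCT)

_MASS_H = MONO_MASS["H"]
_MASS_CL = MONO_MASS["Cl"]


@dataclass(frozen=True)
class EnumerationLimits:
    """Elemental limits and plausibility rules for formula enumeration."""

    max_c: int = 100
    max_h: int = 250
    max_o: int = 80
    max_n: int = 4
    max_s: int = 2
    max_p: int = 2
    tol_ppm: float = 0.6
    hc_min: float = 0.3
    hc_max: float = 2.5
    oc_min: float = 0.0
    oc_max: float = 1.0
    nc_min: float = 0.0
    nc_max: float = 1.0
    dbe_min: int = 0
    p_valence: int = 3

    def __post_init__(self) -> None:
        if self.tol_ppm < 0:
            raise ValueError("tolerance must be positive")
        if self.hc_min > self.hc_max or self.oc_min > self.oc_max:
            raise ValueError("ratio windows must be ordered")


DEFAULT_LIMITS = EnumerationLimits()


@dataclass
class Spectrum:
    """One sample's exported peak list with replicate/blank metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    sn: np.ndarray
    sample_id: str = "sample"
    source: str = ""
    day: float = float("nan")
    replicate_set: str = ""
    is_blank: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sn = np.asarray(self.sn, dtype=float)
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        self.sn = self.sn[order]

    def __len__(self) -> int:
        return self.mz.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity, "sn": self.sn})


@dataclass
class Assignment:
    """A (peak, neutral formula, ion species) triple with mass error."""

    sample_id: str
    peak_index: int
    mz: float
    intensity: float
    sn: float
    formula: Formula
    species: str
    error_ppm: float
    # isotope evidence, filled by the verifier
    n_daughters: int = 0
    samples_confirmed: int = 0
    confirmed: bool = False
    strict_mode: bool = False


def ion_mz(neutral_mass: float, species: str) -> float:
    """m/z of the singly charged anion formed from a neutral of given mass."""
    if species == DEPROTONATED:
        return neutral_mass - _MASS_H + ELECTRON_MASS
    if species == CHLORIDE_ADDUCT:
        return neutral_mass + _MASS_CL + ELECTRON_MASS
    raise ValueError(f"unknown ion species {species!r}")


def neutral_mass_from_ion(mz: float, species: str) -> float:
    """Neutral mass recovered from an observed singly charged anion m/z.

    Deprotonated: M = mz + m(1H) - m(e); chloride adduct:
    M = mz - m(35Cl) - m(e). Raises if the result is non-positive.
    """
    if species == DEPROTONATED:
        m = mz + _MASS_H - ELECTRON_MASS
    elif species == CHLORIDE_ADDUCT:
        m = mz - _MASS_CL - ELECTRON_MASS
    else:
        raise ValueError(f"unknown ion species {species!r}")
    if m <= 0:
        raise ValueError(f"non-positive neutral mass {m:.5f} from m/z {mz}")
    return m


# Named rule violations, in evaluation order.
V_ELEMENT_LIMIT = "element count limit"
V_MIN_COMPOSITION = "minimum C1H1O1"
V_H_BOUND = "H <= 2C + 2 + N"
V_HC_WINDOW = "H:C window"
V_OC_WINDOW = "O:C window"
V_NC_WINDOW = "N:C window"
V_P_O = "P < O + 1"
V_S_O = "S < O + 1"
V_O_PER_P = "at least 1 O per P"
V_O_PER_S = "at least 1 O per S"
V_HETERO = "heteroelement co-occurrence"
V_NITROGEN = "nitrogen rule"
V_DBE = "double bond equivalent"


def passes_constraints(
    f: Formula, limits: EnumerationLimits = DEFAULT_LIMITS
) -> Optional[str]:
    """Check the chemical plausibility rules; return the first violated
    rule's name, or ``None`` when the formula passes.

    Rules (fixed order): element limits; minimum composition C1H1O1;
    H <= 2C + 2 + N; H:C, O:C and N:C windows; P < O + 1; S < O + 1;
    at least one O per P and per S; no heteroelement (N, S, P)
    co-occurrence; nitrogen rule on the neutral nominal mass; integer
    DBE not below the configured minimum.
    """
    if not f.is_valid:
        raise ValueError("negative element count")
    if (
        f.C > limits.max_c
        or f.H > limits.max_h
        or f.O > limits.max_o
        or f.N > limits.max_n
        or f.S > limits.max_s
        or f.P > limits.max_p
        or f.Cl > 0
    ):
        return V_ELEMENT_LIMIT
    if f.C < 1 or f.H < 1 or f.O < 1:
        return V_MIN_COMPOSITION
    if f.H > 2 * f.C + 2 + f.N:
        return V_H_BOUND
    hc = f.H / f.C
    if not (limits.hc_min <= hc <= limits.hc_max):
        return V_HC_WINDOW
    oc = f.O / f.C
    if not (limits.oc_min <= oc <= limits.oc_max):
        return V_OC_WINDOW
    nc = f.N / f.C
    if not (limits.nc_min <= nc <= limits.nc_max):
        return V_NC_WINDOW
    if not f.P < f.O + 1:
        return V_P_O
    if not f.S < f.O + 1:
        return V_S_O
    if f.P > 0 and f.O < f.P:
        return V_O_PER_P
    if f.S > 0 and f.O < f.S:
        return V_O_PER_S
    if sum(1 for x in (f.N, f.S, f.P) if x > 0) > 1:
        return V_HETERO
    if nominal_mass(f) % 2 != f.N % 2:
        return V_NITROGEN
    dbe = double_bond_equivalents(f, limits.p_valence)
    if abs(dbe - round(dbe)) > 1e-9 or dbe < limits.dbe_min:
        return V_DBE
    return None


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _base_grid(limits: EnumerationLimits):
    """Precompute the (heteroatom class x C x O) lattice of base masses.

    H is solved from the mass residual per query, so the per-mass work is a
    handful of vectorized operations over this fixed lattice.
    """
    classes = [(0, 0, 0)]
    classes += [(n, 0, 0) for n in range(1, limits.max_n + 1)]
    classes += [(0, s, 0) for s in range(1, limits.max_s + 1)]
    classes += [(0, 0, p) for p in range(1, limits.max_p + 1)]

    c_vals = np.arange(1, limits.max_c + 1)
    o_vals = np.arange(1, limits.max_o + 1)
    cc, oo = np.meshgrid(c_vals, o_vals, indexing="ij")
    cc = cc.ravel()
    oo = oo.ravel()

    base, Cs, Os, Ns, Ss, Ps = [], [], [], [], [], []
    for n, s, p in classes:
        het = n * MONO_MASS["N"] + s * MONO_MASS["S"] + p * MONO_MASS["P"]
        base.append(12.0 * cc + MONO_MASS["O"] * oo + het)
        Cs.append(cc)
        Os.append(oo)
        Ns.append(np.full_like(cc, n))
        Ss.append(np.full_like(cc, s))
        Ps.append(np.full_like(cc, p))
    return (
        np.concatenate(base),
        np.concatenate(Cs),
        np.concatenate(Os),
        np.concatenate(Ns),
        np.concatenate(Ss),
        np.concatenate(Ps),
    )


def enumerate_candidates(
    neutral_mass: float, limits: EnumerationLimits = DEFAULT_LIMITS
) -> list[Formula]:
    """All neutral formulae within limits whose monoisotopic mass matches
    the target within ``limits.tol_ppm`` (relative tolerance on the
    neutral mass), sorted by absolute mass error.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    base, cc, oo, nn, ss, pp = _base_grid(limits)
    tol_da = limits.tol_ppm * 1e-6 * neutral_mass
    resid_lo = neutral_mass - tol_da - base
    resid_hi = neutral_mass + tol_da - base
    h_lo = np.ceil(resid_lo / _MASS_H).astype(np.int64)
    h_hi = np.floor(resid_hi / _MASS_H).astype(np.int64)
    np.clip(h_lo, 1, None, out=h_lo)
    np.clip(h_hi, None, limits.max_h, out=h_hi)
    idx = np.nonzero(h_hi >= h_lo)[0]

    out: list[tuple[float, Formula]] = []
    for i in idx:
        for h in range(int(h_lo[i]), int(h_hi[i]) + 1):
            f = Formula(
                C=int(cc[i]), H=h, O=int(oo[i]),
                N=int(nn[i]), S=int(ss[i]), P=int(pp[i]),
            )
            if passes_constraints(f, limits) is None:
                err = abs(monoisotopic_mass(f) - neutral_mass) / neutral_mass
                if err <= limits.tol_ppm * 1e-6:
                    out.append((err, f))
    out.sort(key=lambda t: (t[0], t[1]))
    return [f for _, f in out]


def assign_peaks(
    s: Spectrum,
    limits: EnumerationLimits = DEFAULT_LIMITS,
    sn_threshold: float = 3.0,
    species: Sequence[str] = ION_SPECIES,
) -> list[Assignment]:
    """Enumerate candidate assignments for every peak with S/N above the
    export threshold, trying each requested ion species. No deduplication
    or resolution is done here; one peak may yield several assignments.
    """
    out: list[Assignment] = []
    for i in range(len(s)):
        if s.sn[i] <= sn_threshold:
            continue
        for sp in species:
            try:
                m = neutral_mass_from_ion(float(s.mz[i]), sp)
            except ValueError:
                continue
            for f in enumerate_candidates(m, limits):
                theo = monoisotopic_mass(f)
                err_ppm = (m - theo) / theo * 1e6
                out.append(
                    Assignment(
                        sample_id=s.sample_id,
                        peak_index=i,
                        mz=float(s.mz[i]),
                        intensity=float(s.intensity[i]),
                        sn=float(s.sn[i]),
                        formula=f,
                        species=sp,
                        error_ppm=err_ppm,
                    )
                )
    return out
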