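"""Chemical descriptors, molecular groups, diversity and ordination of DOM.

Molecular formulae are characterized by elemental ratios, double bond
equivalents and the modified aromaticity index, and binned into 12
non-overlapping molecular groups. Sample-level descriptors (richness,
Shannon diversity, evenness), compositional (clr) PCA, a time-constrained
redundancy analysis, and Spearman color-coding of van Krevelen space
complete the DOM analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.composition import clr as _skbio_clr
from sklearn.decomposition import PCA

from .formula import Formula, double_bond_equivalents, nominal_mass

if TYPE_CHECKING:  # pragma: no cover
    from .assembly import FormulaMatrix


def aromaticity_index(f: Formula) -> float:
    """Modified aromaticity index AImod.

    AImod = (1 + C - O/2 - S - H/2) / (C - O/2 - S - N - P); clamped to 0
    when the denominator is non-positive or the numerator negative, the
    convention of the index for oxygen-rich or saturated formulae.
    """
    num = 1.0 + f.C - 0.5 * f.O - f.S - 0.5 * f.H
    den = f.C - 0.5 * f.O - f.S - f.N - f.P
    if den <= 0 or num < 0:
        return 0.0
    return num / den


# The 12 disjoint molecular-group labels, in cascade order.
GROUP_LABELS = (
    "condensed_polyaromatic",
    "polyphenol",
    "highly_unsaturated_phenolic_o_poor",
    "highly_unsaturated_phenolic_o_rich",
    "peptide_like",
    "saturated_fatty_acid",
    "carbohydrate",
    "unsaturated_aliphatic",
    "unsaturated_aliphatic_heteroatom",
    "remainder_cho",
    "remainder_n",
    "remainder_sp",
)

#: Groups that trigger the stricter isotope-confirmation limits.
STRICT_GROUPS = frozenset(
    {"condensed_polyaromatic", "saturated_fatty_acid", "carbohydrate"}
)


@dataclass(frozen=True)
class MolecularDescriptors:
    formula: Formula
    dbe: float
    aimod: float
    oc: float
    hc: float
    nc: float
    nominal_mass: int
    group: str


def classify_group(f: Formula) -> str:
    """Assign a formula to exactly one of the 12 molecular groups.

    First-match-wins cascade on AImod, H:C, O:C, DBE and heteroatom
    content. The thresholds follow the aromaticity-index classification
    convention for DOM; the cascade order is fixed so the groups are
    disjoint and total by construction.
    """
    ai = aromaticity_index(f)
    hc = f.H / f.C if f.C else 0.0
    oc = f.O / f.C if f.C else 0.0
    dbe = double_bond_equivalents(f)
    if ai >= 0.67:
        return "condensed_polyaromatic"
    if ai > 0.50:
        return "polyphenol"
    if hc < 1.5:
        if oc < 0.5:
            return "highly_unsaturated_phenolic_o_poor"
        return "highly_unsaturated_phenolic_o_rich"
    if f.N > 0 and 1.5 <= hc <= 2.0 and oc <= 0.9:
        return "peptide_like"
    if f.N == 0 and oc < 0.9 and (hc > 2.0 or (hc == 2.0 and dbe == 1)):
        return "saturated_fatty_acid"
    if oc >= 0.9 and 1.5 <= hc <= 2.5:
        return "carbohydrate"
    if 1.5 <= hc <= 2.0:
        if f.S > 0 or f.P > 0:
            return "unsaturated_aliphatic_heteroatom"
        return "unsaturated_aliphatic"
    if f.N > 0:
        return "remainder_n"
    if f.S > 0 or f.P > 0:
        return "remainder_sp"
    return "remainder_cho"


def descriptors(f: Formula) -> MolecularDescriptors:
    return MolecularDescriptors(
        formula=f,
        dbe=double_bond_equivalents(f),
        aimod=aromaticity_index(f),
        oc=f.O / f.C if f.C else 0.0,
        hc=f.H / f.C if f.C else 0.0,
        nc=f.N / f.C if f.C else 0.0,
        nominal_mass=nominal_mass(f),
        group=classify_group(f),
    )


@dataclass(frozen=True)
class DiversitySummary:
    richness: int
    shannon: float
    evenness: float


def diversity(column: Sequence[float] | np.ndarray | pd.Series) -> DiversitySummary:
    """Richness, Shannon index (nats) and Pielou evenness of one sample's
    relative-intensity column. Zeros are absences; intensities need not be
    normalized (the index is scale invariant)."""
    x = np.asarray(column, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("empty column: no nonzero intensities")
    p = x / x.sum()
    richness = int(p.size)
    shannon = float(-(p * np.log(p)).sum())
    evenness = 1.0 if richness == 1 else shannon / np.log(richness)
    return DiversitySummary(richness, shannon, float(evenness))


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # formulae x components
    explained: np.ndarray  # explained-variance fractions
    canonical_r: Optional[float] = None
    p_value: Optional[float] = None


def _relative_columns(rel: pd.DataFrame) -> pd.DataFrame:
    tot = rel.sum(axis=0)
    if (tot <= 0).any():
        bad = tot.index[tot <= 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")
    return rel / tot


def clr_matrix(rel: pd.DataFrame, zero_factor: float = 0.65) -> pd.DataFrame:
    """Centered log-ratio transform of a formulae x samples matrix.

    Zeros are replaced per sample by multiplicative replacement at
    ``zero_factor`` times the smallest nonzero relative intensity of the
    whole matrix, then each sample (column) is log-transformed and
    centered. Returns samples x formulae (one clr row per sample).
    """
    rel = _relative_columns(rel)
    vals = rel.to_numpy().T  # samples x formulae
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("matrix has no nonzero entries")
    delta = zero_factor * nonzero.min()
    out = np.empty_like(vals)
    for i, row in enumerate(vals):
        z = row == 0
        r = row.copy()
        if z.any():
            r[z] = delta
            r[~z] *= 1.0 - z.sum() * delta
        out[i] = r
    out = _skbio_clr(out)
    return pd.DataFrame(out, index=rel.columns, columns=rel.index)


def clr_pca(m: "FormulaMatrix | pd.DataFrame", zero_factor: float = 0.65) -> OrdinationResult:
    """PCA of centered log-transformed relative intensities (SVD based)."""
    rel = m if isinstance(m, pd.DataFrame) else m.intensities
    if rel.shape[1] < 3:
        raise ValueError("need at least 3 samples for ordination")
    x = clr_matrix(rel, zero_factor)
    n_comp = min(x.shape[0] - 1, x.shape[1])
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    arr = x.to_numpy()
    total_var = np.var(arr - arr.mean(axis=0), axis=0).sum()
    if total_var <= 0:
        return OrdinationResult(
            scores=pd.DataFrame(0.0, index=x.index, columns=comp_names),
            loadings=pd.DataFrame(0.0, index=x.columns, columns=comp_names),
            explained=np.zeros(n_comp),
        )
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(arr)
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=x.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=x.columns, columns=comp_names),
        explained=np.asarray(pca.explained_variance_ratio_),
    )


def rda_time(
    m: "FormulaMatrix | pd.DataFrame",
    times: Sequence[float],
    n_perm: int = 999,
    seed: int = 0,
    zero_factor: float = 0.65,
) -> tuple[float, float]:
    """Redundancy analysis with incubation time as the single constraint.

    clr responses are regressed on time; the canonical R is
    sqrt(constrained variance / total variance) and the p value comes
    from permuting time labels (count of permuted R >= observed, with
    +1 correction).
    """
    rel = m if isinstance(m, pd.DataFrame) else m.intensities
    t = np.asarray(times, dtype=float)
    if rel.shape[1] < 4 or np.unique(t).size < 2:
        raise ValueError("need >= 4 samples and >= 2 distinct times")
    y = clr_matrix(rel, zero_factor).to_numpy()
    yc = y - y.mean(axis=0)
    ss_tot = (yc**2).sum()
    if ss_tot <= 0:
        raise ValueError("responses have no variance")

    def _r(tvec: np.ndarray) -> float:
        xc = tvec - tvec.mean()
        ssx = (xc**2).sum()
        if ssx == 0:
            raise ValueError("constant time vector")
        b = xc @ yc / ssx  # per-formula slopes
        ss_fit = float(ssx * (b**2).sum())
        return float(np.sqrt(min(ss_fit / ss_tot, 1.0)))

    r_obs = _r(t)
    rng = np.random.default_rng(seed)
    xc = t - t.mean()
    ssx = (xc**2).sum()
    perms = np.stack([rng.permutation(xc) for _ in range(n_perm)])
    proj = perms @ yc  # n_perm x formulae
    r_perm = np.sqrt(np.minimum((proj**2).sum(axis=1) / (ssx * ss_tot), 1.0))
    p = (1 + int((r_perm >= r_obs - 1e-12).sum())) / (n_perm + 1)
    return r_obs, float(p)


def pc_correlations(
    m: "FormulaMatrix | pd.DataFrame",
    scores: Sequence[float],
    min_occurrence: int = 4,
    quantiles: tuple[float, float] = (0.2, 0.8),
) -> tuple[pd.Series, pd.Index, pd.Index]:
    """Spearman correlation of each formula's relative intensity with PC
    scores, for formulae detected in at least ``min_occurrence`` samples.

    Returns the rho vector and the low-/high-quantile formula sets
    (rho below the lower and above the upper quantile), the two pools of
    compounds likely decreasing/increasing along the gradient.
    """
    rel = m if isinstance(m, pd.DataFrame) else m.intensities
    sc = np.asarray(scores, dtype=float)
    keep = rel.index[(rel > 0).sum(axis=1) >= min_occurrence]
    rhos = {}
    for f in keep:
        y = rel.loc[f].to_numpy()
        if np.all(y == y[0]):  # constant profile: rho undefined, skip
            continue
        rho = stats.spearmanr(y, sc).statistic
        rhos[f] = float(rho)
    rho_s = pd.Series(rhos, dtype=float)
    if rho_s.empty:
        return rho_s, pd.Index([]), pd.Index([])
    lo, hi = rho_s.quantile(quantiles[0]), rho_s.quantile(quantiles[1])
    return rho_s, rho_s.index[rho_s < lo], rho_s.index[rho_s > hi]


def van_krevelen_table(
    m: "FormulaMatrix | pd.DataFrame", seed: int = 0
) -> pd.DataFrame:
    """Plot-ready per-formula table (O:C, H:C, group, mean relative
    intensity) in a seeded random order, so systematic overplotting does
    not bias dense van Krevelen scatter plots."""
    from .formula import parse_formula

    rel = m if isinstance(m, pd.DataFrame) else m.intensities
    rows = []
    for name in rel.index:
        f = name if isinstance(name, Formula) else parse_formula(str(name))
        d = descriptors(f)
        rows.append(
            {
                "formula": f.hill(),
                "oc": d.oc,
                "hc": d.hc,
                "group": d.group,
                "mean_intensity": float(rel.loc[name].mean()),
            }
        )
    table = pd.DataFrame(
        rows, columns=["formula", "oc", "hc", "group", "mean_intensity"]
    )
    rng = np.random.default_rng(seed)
    return table.iloc[rng.permutation(len(table))].reset_index(drop=True)
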