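"""OTU-table statistics for the bottled-water microbiota analysis.

Covers contaminant-OTU removal against negative controls, low-count
filtering, rarefaction resampling, alpha diversity metrics, detection of
"growing" OTUs by integrating total (DAPI) cell counts into a resampling
scheme, core/ubiquitous microbiota determination across water brands, and
inference of assimilable organic carbon from net cell growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def detect_contaminant_otus(
    counts: pd.DataFrame, meta: pd.DataFrame, aggregator: str = "mean"
) -> set[str]:
    """OTUs with higher relative abundance in negative controls than in
    samples.

    ``meta`` must carry a ``habitat`` column; columns with habitat
    ``negctrl`` are the negative controls. ``aggregator`` is ``mean``
    (default) or ``max`` across each group of samples.
    """
    is_ctrl = meta.loc[counts.columns, "habitat"] == "negctrl"
    if not is_ctrl.any():
        warnings.warn("no negative-control samples; contaminant set is empty")
        return set()
    rel = counts / counts.sum(axis=0).replace(0, np.nan)
    agg = getattr(rel.loc[:, is_ctrl.to_numpy()], aggregator)(axis=1)
    agg_s = getattr(rel.loc[:, (~is_ctrl).to_numpy()], aggregator)(axis=1)
    flagged = agg.fillna(0) > agg_s.fillna(0)
    return set(counts.index[flagged])


def filter_min_total(counts: pd.DataFrame, min_total: int = 3) -> pd.DataFrame:
    """Drop OTUs observed with fewer than ``min_total`` reads in total."""
    return counts.loc[counts.sum(axis=1) >= min_total]


def rarefy(
    counts: pd.DataFrame, depth: int = 500, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Resample each column to exactly ``depth`` reads without
    replacement; samples with fewer than ``depth`` reads are omitted."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = counts.columns[counts.sum(axis=0) >= depth]
    out = {}
    for col in keep:
        vec = counts[col].to_numpy(dtype=np.int64)
        out[col] = rng.multivariate_hypergeometric(vec, depth)
    return pd.DataFrame(out, index=counts.index, columns=keep)


@dataclass(frozen=True)
class AlphaMetrics:
    observed: int
    chao1: float
    shannon: float
    simpson: float
    goods_coverage: float


def alpha_metrics(column: Sequence[int] | np.ndarray | pd.Series) -> AlphaMetrics:
    """Observed OTUs, bias-corrected Chao1, Shannon (nats), Simpson
    (1 - sum p^2) and Good's coverage (1 - singletons/reads)."""
    x = np.asarray(column, dtype=np.int64)
    n = int(x.sum())
    if n < 1:
        raise ValueError("column must contain at least one read")
    x = x[x > 0]
    s_obs = int(x.size)
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = x / n
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    goods = 1.0 - f1 / n
    return AlphaMetrics(s_obs, float(chao1), shannon, simpson, float(goods))


def _pearson_vectorized(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of y (otus x samples) against x, with one-sided
    (positive alternative) p values from the t distribution."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / (sx * sy)
    r = np.clip(np.nan_to_num(r, nan=0.0), -0.999999999, 0.999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = stats.t.sf(t, df=n - 2)
    return r, p


@dataclass
class GrowthTestResult:
    """Per-OTU growth statistics: median resampled p, BH-adjusted p,
    median correlation, and the growing flag."""

    table: pd.DataFrame  # columns: median_p, adjusted_p, median_r, growing

    @property
    def growing(self) -> set[str]:
        return set(self.table.index[self.table["growing"]])


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    """Normal draws truncated at zero by redraw."""
    out = rng.normal(mean, sd)
    bad = out <= 0
    tries = 0
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = out <= 0
        tries += 1
        if tries > 1000:  # pragma: no cover - pathological inputs
            out[bad] = np.finfo(float).tiny
            break
    return out


def growing_otus(
    counts: pd.DataFrame,
    days: pd.Series,
    cells: pd.DataFrame,
    iters: int = 100,
    depth: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    alternative: str = "greater",
) -> GrowthTestResult:
    """Detect OTUs whose estimated absolute abundance grows with time.

    Per iteration: a total cell count is drawn for each sample from
    Normal(dapi_mean, dapi_sd) truncated at zero; the OTU table is
    rarefied to ``depth`` (samples below depth omitted); each OTU's
    estimated cells = resampled relative abundance x drawn total; Pearson
    r and a one-sided p value (positive alternative) are computed between
    log(cells + 1) and log(day). The per-OTU median p over ``iters``
    iterations is Benjamini-Hochberg adjusted across OTUs; growing OTUs
    have adjusted median p < ``alpha`` and positive median r.
    """
    missing = [c for c in counts.columns if c not in cells.index]
    if missing:
        raise ValueError(f"missing cell counts for sample(s): {missing}")
    days = days.loc[counts.columns].astype(float)
    if (days < 1).any():
        raise ValueError("days must be >= 1 for the log transform")
    if days.nunique() < 2 or len(counts.columns) < 3:
        raise ValueError("need >= 3 samples over >= 2 distinct days")

    rng = np.random.default_rng(seed)
    mean = cells.loc[counts.columns, "dapi_mean"].to_numpy(dtype=float)
    sd = cells.loc[counts.columns, "dapi_sd"].to_numpy(dtype=float)
    deep_cols = counts.columns[counts.sum(axis=0) >= depth]
    sub = counts[deep_cols]
    col_idx = [counts.columns.get_loc(c) for c in deep_cols]
    x = np.log(days.loc[deep_cols].to_numpy())
    if np.unique(x).size < 2 or len(deep_cols) < 3:
        raise ValueError("too few samples above rarefaction depth")

    ps = np.empty((iters, counts.shape[0]))
    rs = np.empty((iters, counts.shape[0]))
    mat = sub.to_numpy(dtype=np.int64)
    for it in range(iters):
        totals = _truncated_normal(rng, mean, sd)[col_idx]
        rare = np.stack(
            [rng.multivariate_hypergeometric(mat[:, j], depth) for j in range(mat.shape[1])],
            axis=1,
        )
        rel = rare / depth
        est_cells = rel * totals
        y = np.log(est_cells + 1.0)
        r, p = _pearson_vectorized(y, x)
        if alternative == "two-sided":
            p = 2 * np.minimum(p, 1 - p)
        rs[it] = r
        ps[it] = p

    median_p = np.median(ps, axis=0)
    median_r = np.median(rs, axis=0)
    adjusted = multipletests(median_p, method="fdr_bh")[1]
    growing = (adjusted < alpha) & (median_r > 0)
    table = pd.DataFrame(
        {
            "median_p": median_p,
            "adjusted_p": adjusted,
            "median_r": median_r,
            "growing": growing,
        },
        index=counts.index,
    )
    return GrowthTestResult(table)


@dataclass
class CoreSets:
    well_core: set[str]
    early_core: set[str]
    late_core: set[str]

    @property
    def ubiquitous(self) -> set[str]:
        return self.well_core & self.early_core & self.late_core


def core_sets(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    abund: float = 0.005,
    occupancy: float = 0.5,
    n_brands: Optional[int] = None,
    late_day: float = 14,
    strict_brand: bool = False,
) -> CoreSets:
    """Core microbiota in three habitat categories and their intersection.

    Categories: well waters; early bottled waters (day 1); late bottled
    waters (day >= ``late_day``). An OTU credits a brand in a category
    when its relative abundance reaches ``abund`` in at least one of that
    brand's samples there (all samples, with ``strict_brand``); an OTU is
    core when it credits at least ``occupancy x n_brands`` brands.
    """
    meta = meta.loc[counts.columns]
    non_ctrl = meta["habitat"] != "negctrl"
    if n_brands is None:
        n_brands = int(meta.loc[non_ctrl, "brand"].nunique())
    rel = counts / counts.sum(axis=0).replace(0, np.nan)
    need = occupancy * n_brands

    def core_for(mask: pd.Series) -> set[str]:
        cols = counts.columns[mask.to_numpy()]
        if len(cols) == 0:
            raise ValueError("category with zero samples")
        qual = rel[cols].ge(abund)
        brand_of = meta.loc[cols, "brand"]
        credit = qual.T.groupby(brand_of).all() if strict_brand else qual.T.groupby(brand_of).any()
        n_credit = credit.sum(axis=0)
        return set(counts.index[(n_credit >= need).to_numpy()])

    well = core_for(non_ctrl & (meta["water_type"] == "well"))
    early = core_for(non_ctrl & (meta["water_type"] == "bottle") & (meta["day"] == 1))
    late = core_for(
        non_ctrl & (meta["water_type"] == "bottle") & (meta["day"] >= late_day)
    )
    return CoreSets(well, early, late)


def assimilable_carbon(
    cells_start: float, cells_end: float, yield_cells_per_ug: float = 1e7
) -> float:
    """Assimilable organic carbon (ug C / L) inferred from net growth.

    AOC = (cells_end - cells_start) x 1000 / yield, with cell counts in
    cells/mL and the yield factor in cells per ug carbon.
    """
    if yield_cells_per_ug <= 0:
        raise ValueError("yield must be positive")
    if cells_end < cells_start:
        raise ValueError("negative growth: cells_end < cells_start")
    return (cells_end - cells_start) * 1000.0 / yield_cells_per_ug
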