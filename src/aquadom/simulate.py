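"""Ground-truthed synthetic mass spectra and microbial community data.

The generators emulate the statistical structure the downstream analysis
assumes: electrospray-negative peak lists containing deprotonated ions
and chloride adducts of known formulae plus isotopologue daughter peaks
and unassignable noise; blank spectra carrying contaminant formulae;
triplicate structure per source and time point; and OTU tables with a
diverse low-abundance seed community, a few OTUs growing log-linearly
with storage time, negative-control contamination, and total (DAPI) cell
count trajectories rising to >= 1e5 cells/mL. Every generator returns the
planted ground truth alongside the data so recovery can be scored
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import (
    CHLORIDE_ADDUCT,
    DEPROTONATED,
    DEFAULT_LIMITS,
    EnumerationLimits,
    Spectrum,
    enumerate_candidates,
    ion_mz,
    passes_constraints,
)
from .formula import Formula, monoisotopic_mass
from .verifier import theoretical_isotopologues

MASS_WINDOW = (153.0, 1000.0)


@dataclass
class SpectrumDesign:
    """Parameters of one synthetic spectrum.

    ``intensity_model`` gives (mu, sigma) of the log-normal parent
    intensity distribution; ``sn_model`` maps intensity to S/N (default:
    intensity divided by a 2e4 noise floor); ``ion_mix`` is the fraction
    of formulae also emitted as chloride adducts; ``n_daughters`` caps
    the isotopologue daughters emitted per parent ion.
    """

    true_formulae: list[Formula] = field(default_factory=list)
    ion_mix: float = 0.2
    ppm_jitter: float = 0.2
    n_noise_peaks: int = 25
    intensity_model: tuple[float, float] = (math.log(1e7), 0.8)
    sn_model: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]
    n_daughters: int = 4
    #: which formulae ionize as Cl-adducts; None draws Bernoulli(ion_mix)
    #: per formula at emission time (adduct formation is a property of the
    #: molecule, so studies fix this set once across all samples)
    adduct_formulae: Optional[frozenset] = None
    daughter_noise_sd: float = 0.10
    adduct_fraction_of_parent: float = 0.3
    #: noise intensities map to S/N ~ 4 under the default sn_model:
    #: above the export threshold (3) so noise exercises assignment,
    #: below the blank-contaminant threshold (5) so random noise can
    #: never masquerade as a planted blank contaminant
    noise_intensity_model: tuple[float, float] = (math.log(8e4), 0.05)
    noise_guard_da: float = 4.5
    seed: int = 0
    limits: EnumerationLimits = DEFAULT_LIMITS

    def __post_init__(self) -> None:
        if self.ppm_jitter < 0:
            raise ValueError("ppm_jitter must be >= 0")
        if not 0 <= self.ion_mix <= 1:
            raise ValueError("ion_mix must lie in [0, 1]")
        if self.sn_model is None:
            self.sn_model = lambda intensity: np.asarray(intensity) / 2e4
        for f in self.true_formulae:
            rule = passes_constraints(f, self.limits)
            if rule is not None:
                raise ValueError(
                    f"formula {f.hill()} violates enumeration rule: {rule}"
                )


def _jitter(rng: np.random.Generator, mz: float, ppm: float) -> float:
    return mz * (1.0 + rng.normal(0.0, ppm) * 1e-6) if ppm > 0 else mz


def simulate_spectrum(
    design: SpectrumDesign,
    as_blank: bool = False,
    sample_id: str = "sample",
    rng: Optional[np.random.Generator] = None,
    **meta,
) -> tuple[Spectrum, pd.DataFrame]:
    """Emit one spectrum plus its peak-level ground truth.

    Each true formula produces a deprotonated parent (and, for an
    ``ion_mix`` fraction, a chloride adduct) at the theoretical m/z
    perturbed by Normal(0, ppm_jitter) ppm, with the ``n_daughters`` most
    intense isotopologue daughters at theoretical shifts and
    multiplicatively perturbed intensity ratios. Noise peaks are placed
    uniformly over the 153-1000 Da window, keeping a guard distance from
    every other peak so that ground truth stays unambiguous.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    mu, sigma = design.intensity_model
    mzs: list[float] = []
    ints: list[float] = []
    truth_rows: list[dict] = []

    for f in design.true_formulae:
        if design.adduct_formulae is not None:
            emit_adduct = f in design.adduct_formulae
        else:
            emit_adduct = rng.random() < design.ion_mix
        neutral = monoisotopic_mass(f)
        parent_int = float(rng.lognormal(mu, sigma))
        for species, scale in (
            (DEPROTONATED, 1.0),
            (CHLORIDE_ADDUCT, design.adduct_fraction_of_parent),
        ):
            if species == CHLORIDE_ADDUCT and not emit_adduct:
                continue
            theo = ion_mz(neutral, species)
            obs = _jitter(rng, theo, design.ppm_jitter)
            ion_int = parent_int * scale
            mzs.append(obs)
            ints.append(ion_int)
            truth_rows.append(
                {"mz": obs, "role": "parent", "formula": f.hill(), "species": species}
            )
            if design.n_daughters > 0:
                pattern = theoretical_isotopologues(f, species, n_max=design.n_daughters)
                for shift, ratio in zip(pattern.shifts, pattern.ratios):
                    dmz = _jitter(rng, theo + shift, design.ppm_jitter)
                    noise = (
                        rng.lognormal(0.0, design.daughter_noise_sd)
                        if design.daughter_noise_sd > 0
                        else 1.0
                    )
                    mzs.append(dmz)
                    ints.append(ion_int * ratio * noise)
                    truth_rows.append(
                        {
                            "mz": dmz,
                            "role": "daughter",
                            "formula": f.hill(),
                            "species": species,
                        }
                    )

    nmu, nsigma = design.noise_intensity_model
    guard = design.noise_guard_da
    existing = sorted(mzs)
    placed = 0
    attempts = 0
    while placed < design.n_noise_peaks and attempts < design.n_noise_peaks * 200:
        attempts += 1
        cand = float(rng.uniform(*MASS_WINDOW))
        if existing:
            i = np.searchsorted(existing, cand)
            near = []
            if i > 0:
                near.append(existing[i - 1])
            if i < len(existing):
                near.append(existing[i])
            if any(abs(cand - x) < guard for x in near):
                continue
        import bisect

        bisect.insort(existing, cand)
        mzs.append(cand)
        ints.append(float(rng.lognormal(nmu, nsigma)))
        truth_rows.append({"mz": cand, "role": "noise", "formula": "", "species": ""})
        placed += 1

    mz_arr = np.asarray(mzs)
    int_arr = np.asarray(ints)
    sn_arr = np.asarray(design.sn_model(int_arr), dtype=float)
    spec = Spectrum(
        mz=mz_arr,
        intensity=int_arr,
        sn=sn_arr,
        sample_id=sample_id,
        is_blank=as_blank,
        **meta,
    )
    truth = pd.DataFrame(
        truth_rows, columns=["mz", "role", "formula", "species"]
    ).sort_values("mz").reset_index(drop=True)
    return spec, truth


# ---------------------------------------------------------------------------
# Replicate study
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """A replicate study: sources x times x replicates, plus blanks.

    All sources share the study-wide true formulae (the refractory DOM
    background is common to related waters); each replicate set gets
    ``n_singlets_per_set`` extra formulae injected into exactly one
    replicate to exercise the replicate filter, and ``n_contaminants``
    formulae appear in every sample and in the blanks at S/N > 5.
    """

    sources: tuple[str, ...] = ("water1", "water2", "water3")
    days: tuple[float, ...] = (1, 7, 28, 56)
    reps: int = 3
    n_formulae: int = 300
    n_singlets_per_set: int = 2
    n_contaminants: int = 5
    n_blanks: int = 20
    spectrum: SpectrumDesign = field(default_factory=SpectrumDesign)
    seed: int = 0


@dataclass
class StudyTruth:
    true_formulae: set[Formula]
    singlets: dict[str, set[Formula]]  # replicate set -> injected formulae
    contaminants: set[Formula]

    @property
    def n_singlets(self) -> int:
        return sum(len(v) for v in self.singlets.values())


class MzGuard:
    """Tracks emitted ion and isotopologue positions so newly drawn
    formulae cannot collide with them.

    A collision (a parent ion landing within the guard distance of
    another formula's parent or daughter position, or vice versa) would
    make planted-count bookkeeping ambiguous; real spectra contain such
    isobaric interferences, the ground-truthed generator deliberately
    avoids them.
    """

    def __init__(self, guard_da: float = 0.01, n_daughters: int = 6) -> None:
        self.guard_da = guard_da
        self.n_daughters = n_daughters
        self._positions: list[float] = []

    def _formula_positions(self, f: Formula) -> list[float]:
        out = []
        neutral = monoisotopic_mass(f)
        for species in (DEPROTONATED, CHLORIDE_ADDUCT):
            parent = ion_mz(neutral, species)
            out.append(parent)
            pattern = theoretical_isotopologues(f, species, n_max=self.n_daughters)
            out.extend(parent + s for s in pattern.shifts)
        return out

    def clashes(self, f: Formula) -> bool:
        import bisect

        for pos in self._formula_positions(f):
            i = bisect.bisect_left(self._positions, pos)
            for j in (i - 1, i):
                if 0 <= j < len(self._positions):
                    if abs(self._positions[j] - pos) < self.guard_da:
                        return True
        return False

    def add(self, f: Formula) -> None:
        import bisect

        for pos in self._formula_positions(f):
            bisect.insort(self._positions, pos)


def _ambiguous(f: Formula, limits: EnumerationLimits, guard_ppm: float) -> bool:
    """True when the formula's ions admit a competing assignment.

    Checks (a) another candidate within ``guard_ppm`` of the formula's
    own neutral mass, and (b) any candidate under the *other* ion-species
    interpretation of either of its ion peaks. Planting only uniquely
    assignable formulae keeps recovery scoring against the ground truth
    exact.
    """
    from .engine import neutral_mass_from_ion

    wide = replace(limits, tol_ppm=guard_ppm)
    neutral = monoisotopic_mass(f)
    if len(enumerate_candidates(neutral, wide)) > 1:
        return True
    for species, other in (
        (DEPROTONATED, CHLORIDE_ADDUCT),
        (CHLORIDE_ADDUCT, DEPROTONATED),
    ):
        peak = ion_mz(neutral, species)
        try:
            neutral2 = neutral_mass_from_ion(peak, other)
        except ValueError:
            continue
        if enumerate_candidates(neutral2, wide):
            return True
    return False


def random_formulae(
    n: int,
    rng: np.random.Generator,
    limits: EnumerationLimits = DEFAULT_LIMITS,
    exclude: Iterable[Formula] = (),
    class_weights: Mapping[str, float] | None = None,
    guard: Optional[MzGuard] = None,
    unique_within_ppm: Optional[float] = 2.0,
) -> list[Formula]:
    """Draw distinct DOM-like formulae satisfying the enumeration rules,
    with deprotonated-ion m/z inside the instrument window.

    Compound classes are drawn with weights (default 70% CHO, 20% CHON
    with 1-2 N, 10% CHOS), C from 8-36 and plausible O and H ranges,
    rejection-sampling until the constraints pass.
    """
    weights = dict(class_weights or {"CHO": 0.7, "CHON": 0.2, "CHOS": 0.1})
    labels = list(weights)
    probs = np.array([weights[k] for k in labels], dtype=float)
    probs /= probs.sum()
    out: list[Formula] = []
    seen: set[Formula] = set(exclude)
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200000:
            raise RuntimeError("formula sampling did not converge")
        cls = labels[rng.choice(len(labels), p=probs)]
        c = int(rng.integers(8, 37))
        o = int(rng.integers(2, min(c, 20) + 1))
        n_at = int(rng.integers(1, 3)) if cls == "CHON" else 0
        s_at = 1 if cls == "CHOS" else 0
        # H:C mostly below 1.7: refractory soil-derived DOM is dominated
        # by unsaturated compounds
        h_max = min(2 * c + 2 + n_at, int(1.7 * c))
        h = int(rng.integers(max(4, int(0.5 * c)), h_max + 1))
        f = Formula(C=c, H=h, O=o, N=n_at, S=s_at)
        if f in seen:
            continue
        if passes_constraints(f, limits) is not None:
            continue
        mz = ion_mz(monoisotopic_mass(f), DEPROTONATED)
        if not (MASS_WINDOW[0] <= mz <= MASS_WINDOW[1] - 6):
            continue
        if unique_within_ppm is not None and _ambiguous(f, limits, unique_within_ppm):
            continue
        if guard is not None:
            if guard.clashes(f):
                continue
            guard.add(f)
        seen.add(f)
        out.append(f)
    return out


def simulate_replicate_study(
    design: StudyDesign,
) -> tuple[list[Spectrum], dict[str, pd.DataFrame], StudyTruth]:
    """Generate the full replicate study: sample spectra with replicate
    set labels, blank spectra, and the planted ground truth."""
    if not design.sources or not design.days or design.reps < 1:
        raise ValueError("need >= 1 source, >= 1 time, >= 1 replicate")
    rng = np.random.default_rng(design.seed)
    guard = MzGuard()
    base = random_formulae(design.n_formulae, rng, design.spectrum.limits, guard=guard)
    contaminants = random_formulae(
        design.n_contaminants, rng, design.spectrum.limits, exclude=base, guard=guard
    )
    n_sets = len(design.sources) * len(design.days)
    singlet_pool = random_formulae(
        design.n_singlets_per_set * n_sets,
        rng,
        design.spectrum.limits,
        exclude=list(base) + list(contaminants),
        guard=guard,
    )

    all_planted = list(base) + list(contaminants) + list(singlet_pool)
    adducts = frozenset(
        f for f in all_planted if rng.random() < design.spectrum.ion_mix
    )

    spectra: list[Spectrum] = []
    truths: dict[str, pd.DataFrame] = {}
    singlets: dict[str, set[Formula]] = {}
    k = 0
    for source in design.sources:
        for day in design.days:
            rep_set = f"{source}_d{day:g}"
            injected = set(
                singlet_pool[k * design.n_singlets_per_set : (k + 1) * design.n_singlets_per_set]
            )
            k += 1
            singlets[rep_set] = injected
            lucky = int(rng.integers(design.reps))
            for r in range(design.reps):
                formulae = list(base) + list(contaminants)
                if r == lucky:
                    formulae += list(injected)
                d = replace(
                    design.spectrum,
                    true_formulae=formulae,
                    adduct_formulae=adducts,
                )
                sid = f"{rep_set}_r{r + 1}"
                spec, truth = simulate_spectrum(
                    d,
                    sample_id=sid,
                    rng=rng,
                    source=source,
                    day=float(day),
                    replicate_set=rep_set,
                )
                spectra.append(spec)
                truths[sid] = truth

    for b in range(design.n_blanks):
        d = replace(
            design.spectrum,
            true_formulae=list(contaminants),
            adduct_formulae=adducts,
        )
        sid = f"blank_{b + 1}"
        spec, truth = simulate_spectrum(
            d, as_blank=True, sample_id=sid, rng=rng, replicate_set="blanks"
        )
        spectra.append(spec)
        truths[sid] = truth

    truth = StudyTruth(
        true_formulae=set(base),
        singlets=singlets,
        contaminants=set(contaminants),
    )
    return spectra, truths, truth


# ---------------------------------------------------------------------------
# Microbial community
# ---------------------------------------------------------------------------

@dataclass
class CommunityDesign:
    """Synthetic bottled-water community with planted growers.

    Growing OTUs interpolate log-linearly (log cells vs log day) from
    their start to end density over the sampled days; the non-growing
    seed community is a constant Dirichlet background. Negative-control
    samples contain only the designated contaminant OTUs. Total-count
    (DAPI) trajectories follow the true totals with multiplicative noise
    of coefficient of variation ``cellcount_cv``, truncated at zero.
    """

    n_otus: int = 80
    n_brands: int = 3
    days: tuple[float, ...] = (1, 7, 14, 28, 56)
    reps_per_point: int = 3
    reads_model: float = 2639.0
    #: day by which post-bottling growth is complete; cells stay at the
    #: end density afterwards (growth finishes within about a week)
    plateau_day: float = 7.0
    growth_otus: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "OTU_1": (1e3, 1.2e5),
            "OTU_2": (5e2, 6e4),
        }
    )
    background_cells: float = 9e3
    background_abundance: float = 0.1  # Dirichlet concentration
    #: draw an independent seed-community profile per brand (each water
    #: has a characteristic composition; only the growers are shared)
    brand_specific_background: bool = True
    negctrl_otus: Mapping[str, float] = field(
        default_factory=lambda: {"OTU_ctam1": 0.12, "OTU_ctam2": 0.08}
    )
    sample_carryover: float = 1e-4  # contaminant rel. abundance in real samples
    n_negctrl: int = 3
    include_wells: bool = True
    cellcount_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_model < 1:
            raise ValueError("reads_model must be >= 1")
        for otu, (c0, c1) in self.growth_otus.items():
            if c0 < 0 or c1 < 0:
                raise ValueError(f"negative growth trajectory for {otu}")


@dataclass
class CommunityTruth:
    growing: set[str]
    contaminants: set[str]
    true_totals: pd.Series  # cells/mL per sample


def _growth_curve(
    day: float, days: Sequence[float], c0: float, c1: float, plateau: float
) -> float:
    """Log-linear rise (log cells vs log day) up to the plateau day,
    constant at the end density afterwards."""
    d0 = math.log(min(days))
    d1 = math.log(min(max(days), plateau))
    if day >= plateau or d1 <= d0:
        return c1
    frac = (math.log(day) - d0) / (d1 - d0)
    return math.exp(math.log(c0) + frac * (math.log(c1) - math.log(c0)))


def simulate_community(
    design: CommunityDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CommunityTruth]:
    """Generate (counts, metadata, cell counts, truth).

    Counts are OTUs x samples integer reads drawn multinomially from the
    relative cell abundances with Poisson library sizes around
    ``reads_model``. Metadata columns: brand, habitat, water_type, day,
    replicate, dapi_mean, dapi_sd.
    """
    rng = np.random.default_rng(design.seed)
    growers = list(design.growth_otus)
    contaminants = list(design.negctrl_otus)
    n_background = design.n_otus - len(growers) - len(contaminants)
    if n_background < 1:
        raise ValueError("n_otus too small for the designated OTUs")
    background = [f"OTU_bg{i + 1}" for i in range(n_background)]
    otus = growers + contaminants + background

    conc = np.full(n_background, design.background_abundance)
    shared_profile = rng.dirichlet(conc)

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    totals = {}
    cell_rows = {}

    def add_sample(sid, brand, habitat, water_type, day, rep, cell_vec):
        total = float(cell_vec.sum())
        rel = cell_vec / total
        reads = max(int(rng.poisson(design.reads_model)), 1)
        cols[sid] = rng.multinomial(reads, rel)
        dapi_mean = float(
            _truncated_pos(rng, total, design.cellcount_cv * total)
        )
        meta_rows.append(
            {
                "sample_id": sid,
                "brand": brand,
                "habitat": habitat,
                "water_type": water_type,
                "day": day,
                "replicate": rep,
                "dapi_mean": dapi_mean,
                "dapi_sd": design.cellcount_cv * dapi_mean,
            }
        )
        totals[sid] = total
        cell_rows[sid] = {"dapi_mean": dapi_mean, "dapi_sd": design.cellcount_cv * dapi_mean}

    for b in range(design.n_brands):
        brand = f"brand{b + 1}"
        profile = (
            rng.dirichlet(conc) if design.brand_specific_background else shared_profile
        )
        bg_cells = design.background_cells * profile
        if design.include_wells:
            for r in range(design.reps_per_point):
                cell_vec = _community_cells(
                    design, min(design.days), bg_cells, growers, contaminants
                )
                add_sample(
                    f"{brand}_well_r{r + 1}", brand, "plankton", "well", 1.0, r + 1,
                    cell_vec,
                )
        for day in design.days:
            for r in range(design.reps_per_point):
                cell_vec = _community_cells(
                    design, day, bg_cells, growers, contaminants
                )
                add_sample(
                    f"{brand}_d{day:g}_r{r + 1}", brand, "plankton", "bottle",
                    float(day), r + 1, cell_vec,
                )

    # negative controls: only the designated contaminant OTUs (plus noise)
    for i in range(design.n_negctrl):
        rel = np.zeros(len(otus))
        for j, otu in enumerate(contaminants):
            rel[len(growers) + j] = design.negctrl_otus[otu]
        rel /= rel.sum()
        sid = f"negctrl_{i + 1}"
        reads = max(int(rng.poisson(design.reads_model / 4)), 1)
        cols[sid] = rng.multinomial(reads, rel)
        meta_rows.append(
            {
                "sample_id": sid,
                "brand": "none",
                "habitat": "negctrl",
                "water_type": "control",
                "day": np.nan,
                "replicate": i + 1,
                "dapi_mean": 1.0,
                "dapi_sd": 0.0,
            }
        )
        cell_rows[sid] = {"dapi_mean": 1.0, "dapi_sd": 0.0}

    counts = pd.DataFrame(cols, index=otus, dtype=np.int64)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    cells = pd.DataFrame(cell_rows).T
    truth = CommunityTruth(
        growing=set(growers),
        contaminants=set(contaminants),
        true_totals=pd.Series(totals),
    )
    return counts, meta, cells, truth


def _community_cells(design, day, bg_cells, growers, contaminants):
    grow = np.array(
        [
            _growth_curve(
                day, design.days, *design.growth_otus[o], design.plateau_day
            )
            for o in growers
        ]
    )
    total_real = grow.sum() + bg_cells.sum()
    contam = np.array(
        [design.sample_carryover * total_real for _ in contaminants]
    )
    return np.concatenate([grow, contam, bg_cells])


def _truncated_pos(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0:
        return mean
    x = rng.normal(mean, sd)
    while x <= 0:
        x = rng.normal(mean, sd)
    return x
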