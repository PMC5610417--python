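# Methods

This note documents the models and procedures implemented in `aquadom`,
the assumptions behind them, the tunable parameters, and what the
synthetic data generators do and do not emulate.

## 1. Molecular-formula assignment

### Exact-mass arithmetic

All masses derive from an embedded table of isotope masses and natural
abundances (`aquadom.isotope_data`). Singly charged negative ions are
supported in two species:

- deprotonated molecule, m/z = M − m(¹H) + m(e⁻)
- chloride adduct, m/z = M + m(³⁵Cl) + m(e⁻)

The electron mass (0.00055 Da) is included in both directions of the
ion ↔ neutral conversion: at a 0.6 ppm tolerance it is a ~2 ppm effect
below 300 Da and cannot be neglected.

### Constrained enumeration

`enumerate_candidates` returns every neutral formula within the
elemental limits (default C₁₀₀H₂₅₀O₈₀N₄S₂P₂) whose monoisotopic mass
matches the target within the tolerance. The tolerance (default
0.6 ppm) is applied on the *neutral mass*; applying it on the ion m/z
would differ negligibly, but the choice is fixed and documented here.
Candidates must pass, in a fixed evaluation order: element limits,
minimum composition C₁H₁O₁, H ≤ 2C + 2 + N, H:C ∈ [0.3, 2.5],
O:C ∈ [0, 1], N:C ∈ [0, 1], P < O + 1, S < O + 1, at least one O per P
and per S (read as O ≥ P and O ≥ S, consistent with the adjacent
inequalities), no co-occurrence of N, S and P, the nitrogen rule
(evaluated on the neutral molecule's nominal mass), and an integer DBE
not below `dbe_min`.

Two conventions are configurable because the field uses both:

- **DBE**: 1 + C − H/2 + N/2 + P/2 with trivalent phosphorus (default);
  pentavalent P is selectable. "Positive integer DBE" is implemented as
  DBE ∈ ℤ with `dbe_min = 0` by default (common practice for DOM, where
  fully saturated acyclic molecules are legitimate); `dbe_min = 1` gives
  the literal reading. For C,H,N,O,S,P molecules, DBE-integrality is
  mathematically equivalent to the nitrogen rule, so the default choice
  only affects the DBE ≥ minimum bound.
- **Search order**: the implementation iterates heteroatom class, then
  (C, O) on a precomputed lattice, solving H from the mass residual.
  This is an optimization only; correctness is defined by equivalence
  with an exhaustive full-lattice scan, which the test suite enforces on
  100 random masses.

### Isotope-pattern verification

For each candidate, theoretical isotopologue daughters (¹³C, ²H, ¹⁵N,
¹⁷O, ¹⁸O, ³³S, ³⁴S, ³⁶S, and ³⁷Cl for the adduct chlorine; P excluded as
monoisotopic) are generated by multinomial expansion, including
multi-substitution species (¹³C₂, ¹³C + ³⁷Cl, ...). Fine-structure peaks
closer than the instrument-resolution parameter (default 0.0005 Da) are
merged by abundance-weighted mass; the 10 most intense daughters are
kept. The untruncated expansion sums to 1, which the tests check against
an independent convolution oracle.

A daughter *matches* when a spectrum peak lies within the mass tolerance
of the **candidate ion's theoretical m/z plus the expected shift**, and
its intensity ratio to the parent is within ±40% (relative) of the
expected ratio. Anchoring on the theoretical position keeps the daughter
check independent of the parent peak's own mass error; anchoring on the
observed parent would add the two errors in quadrature and was observed
to make confirmation of borderline assignments irreproducible across
replicates. The nearest in-tolerance peak is taken, ties broken by
higher intensity. One matched daughter confirms a formula; chloride
adducts need two (their abundant ³⁷Cl daughter makes this cheap for true
assignments and expensive for false ones).

Stricter limits — halved tolerance (0.3 ppm) and halved ratio window
(±20%) — are applied automatically when the candidate contains N, S or P
or classifies as condensed polyaromatic, saturated fatty acid or
carbohydrate. The ±40% window is read as a relative deviation of the
observed/expected ratio; classification feeds verification one-way (the
classifier needs no isotope data, so there is no circularity).

### Resolution of multiple assignments

Candidates for one peak are ranked by a strict preference cascade:

1. compound classes that dominate environmental samples — CHO, CHON,
   CHON₂, CHOS — outrank all others (CHO is included with the listed
   heteroatom classes: excluding it would discard the bulk of DOM
   against any heteroatom alternative; the set has no internal ranking);
2. more matched daughter peaks, then isotope confirmation across more
   samples;
3. longer homologous series, max of the CH₂- and CO₂-based series;
   chains must be contiguous, and the pool is the union of candidate
   formulae across all samples' assignments (the only non-circular
   reading available at resolution time);
4. smaller |mass error|, then lexicographic formula order — resolution
   is a total order and permutation-invariant.

After resolution, assignments sitting on isotopologue peaks of more
intense assignments (within 2 ppm of an expected daughter position,
intensity-descending pass) are excluded: those peaks are daughters, not
monoisotopic ions, and reporting them as formulae would double-count.
Intensities of a formula observed deprotonated and as a Cl-adduct are
then summed per sample.

### Assembly and filters

Per-sample tables are aligned on exact formulae (not masses) into a
formulae × samples matrix. Filters run in a fixed order and only ever
remove:

1. **confirmation** — formulae never isotope-confirmed in any sample are
   dropped;
2. **blank filter** — a formula assigned to a peak with S/N > 5 in any
   blank is a contaminant and is deleted from all samples (the blank
   requirement is presence, not confirmation);
3. **replicate filter** — within each replicate set (same source and
   time) of size ≥ 2, a formula present in exactly one member is zeroed
   in that set; single-member sets are exempt. Zeroing is per set: a
   formula legitimately replicated elsewhere survives there.

Columns are renormalized to relative intensities (relative to total
*assigned* intensity — the only total that exists at this stage) after
each removal; the chain is idempotent.

## 2. DOM characterization

- **AImod** = (1 + C − O/2 − S − H/2) / (C − O/2 − S − N − P), clamped
  to 0 for non-positive denominator or negative numerator.
- **12 molecular groups**, first-match-wins cascade: condensed
  polyaromatic (AImod ≥ 0.67); polyphenol (AImod > 0.50); highly
  unsaturated phenolic, O-poor / O-rich split at O:C = 0.5 (H:C < 1.5);
  peptide-like (N > 0, 1.5 ≤ H:C ≤ 2.0, O:C ≤ 0.9); saturated fatty acid
  (N = 0, O:C < 0.9, H:C > 2.0 or H:C = 2.0 with DBE = 1); carbohydrate
  (O:C ≥ 0.9, 1.5 ≤ H:C ≤ 2.5); unsaturated aliphatic, with and without
  S/P; three remainder classes split by heteroatom content. The cascade
  is total and disjoint by construction (property-tested over random
  formulae). The thresholds follow the aromaticity-index classification
  convention; they are configuration, not ground truth, because the
  original grouping table is not public.
- **Diversity** per sample: richness (nonzero formulae), Shannon index
  in nats, Pielou evenness H/ln R (1 when R = 1); all scale-invariant.
- **clr ordination**: zeros are replaced per sample by multiplicative
  replacement at 0.65 × the smallest nonzero relative intensity of the
  matrix (factor configurable), then each sample is log-transformed and
  centered (clr rows sum to 0). PCA is SVD-based on the sample-centered
  clr matrix; explained-variance fractions sum to 1.
- **RDA with time as the single constraint**: clr responses regressed on
  time; canonical R = √(constrained SS / total SS); p from label
  permutation with +1 correction. Exactly linear responses give R = 1.
- **Spearman color-coding**: per-formula rho against PC scores for
  formulae detected ≥ 4 times (average ranks for ties; constant
  profiles skipped as undefined); the < 20% and > 80% rho quantiles
  define the likely-decreasing and likely-increasing compound pools.
- **van Krevelen tables** are emitted in a seeded random order to avoid
  systematic overplotting.

## 3. Microbiota procedures

- **Contaminant OTUs**: mean relative abundance in negative controls
  exceeds mean relative abundance in samples (max-based aggregation is
  configurable, since the defining rule does not name an aggregator). OTUs with fewer than 3 total reads are dropped.
- **Rarefaction** at 500 reads per sample without replacement
  (multivariate hypergeometric); shallower samples are omitted.
- **Alpha metrics**: observed OTUs, bias-corrected Chao1
  S + F₁(F₁−1)/(2(F₂+1)), Shannon (nats), Simpson (1 − Σp²), Good's
  coverage 1 − F₁/N.
- **Growing OTUs**: per iteration, a total cell count per sample is
  drawn from Normal(DAPI mean, DAPI SD) truncated at zero by redraw; the
  table is rarefied; per-OTU estimated cells = resampled relative
  abundance × drawn total; Pearson r and a one-sided p (positive
  alternative, matching the definition of growth; two-sided with a sign
  gate is configurable) between log(cells + 1) and log(day). Median p
  over 100 iterations is BH-adjusted across OTUs; growing means adjusted
  p < 0.05 and positive median r. The test controls false positives
  under the null and detects 100-fold growers with 3 replicates at 5
  time points with essentially full power (both measured in the suite).
- **Core sets**: three categories — well waters, early bottled (day 1),
  late bottled (day ≥ 14). An OTU credits a brand when its relative
  abundance reaches 0.5% in ≥ 1 of the brand's samples in the category
  (an all-samples variant is configurable; the two printed phrasings of
  the rule do not pin this down); core membership needs ≥ 50% of the 12
  brands; ubiquitous = intersection of the three cores. Lowering either
  threshold can only grow a core (monotonicity is tested).
- **AOC** = (cells_end − cells_start) × 1000 / yield, in µg C/L, with a
  default yield of 10⁷ cells per µg C (configurable; the classical
  growth-yield lineage for drinking-water AOC assays).

## 4. Synthetic data: what it emulates, and what it does not

`simulate_replicate_study` emits peak lists with the structure the
pipeline assumes: deprotonated parents for every planted formula, a
study-level subset (20%) also as Cl-adducts at 30% of parent intensity,
the top-4 isotopologue daughters per ion with 10% log-normal ratio
noise, mass jitter of 0.2 ppm (SD) on every peak, log-normal parent
intensities (median 10⁷), S/N = intensity / 2×10⁴, 25 unassignable noise
peaks per spectrum, 20 blanks carrying 5 contaminant formulae, and
2 singlet formulae injected into one replicate per replicate set.

Deliberate idealizations, all in service of exact ground-truth scoring:

- planted formulae are **uniquely assignable** — no competing candidate
  within 2 ppm of their neutral mass, including under the other ion
  species' interpretation of either ion peak. Real spectra contain
  isobaric interferences; planting them would make "recovered the planted
  formula" ill-defined.
- noise peaks keep a 4.5 Da guard distance from every other peak, so a
  noise peak can never act as a spurious isotopologue; and their
  intensities map to S/N ≈ 4 — above the export threshold (3), below the
  blank threshold (5) — so noise exercises assignment but cannot
  register as a blank contaminant.
- no transients, chromatography, chimeras or sequencing-error profiles;
  intensities are drawn i.i.d. per sample (no planted temporal trend in
  DOM composition, so a time-constrained RDA on simulated spectra is a
  null case; the RDA itself is validated on constructed compositions
  with known structure).

Consequently, passing the recovery tests shows the pipeline's logic and
bookkeeping are correct under realistic noise levels; it does not show
that a real spectrum's isobaric ambiguities would all be resolved
correctly — that is what the preference cascade is for, and it is tested
separately on constructed ambiguous cases.

`simulate_community` plants: a seed community with an independent
Dirichlet(0.1) profile per brand (each water has a characteristic
composition) over a constant 9×10³ cells/mL background; growers rising
log-linearly (log cells vs log day) from ~10³ to ~10⁵–1.2×10⁵ cells/mL
by day 7 and constant after (growth completes within about a week);
multinomial reads with Poisson library sizes around 2639 (the study-scale
mean reads/sample); negative controls containing only the designated
contaminant OTUs; DAPI means tracking true totals with CV 0.2, truncated
at zero. No published distributional description of such seed
communities exists; these defaults are pragmatic choices fixed once.

## 5. Problem sizes and numerical choices

The shipped analyses and tests run at desk scale, chosen as the smallest
sizes at which every statistical property is measurable: the worked
study uses 2 waters × 4 times × 3 replicates with 150 planted formulae
(the full-chain test uses 3 × 4 × 3 with 300); error-control and power
of the growth test use 200 and 100 seeded communities of 40 OTUs;
permutation tests use 199–999 permutations. All randomness flows through
`numpy.random.default_rng` seeds; fixed seeds make every reported number
reproducible bit-for-bit.

Known limitations: single charge state and two ion species only (no
Na⁺/K⁺ adducts, no recalibration of the mass axis); the 12-group
thresholds are a convention, not a measured truth; the homologous-series
pool is the pre-resolution candidate union, which slightly overstates
series support for dense candidate sets; at ~3σ mass-jitter tails a
planted formula can legitimately fail assignment in a replicate, so
planted-count bookkeeping is exact with the shipped seeds but not for
every conceivable seed.
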