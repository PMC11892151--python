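# Methods

This note documents the statistical model behind each `laccscreen` stage, the
rationale for the default parameters, and the package's known limitations.
Defaults describe the study conditions the generators emulate; none were tuned
against the test suite.

## Kinetic quantification

A well's ABTS-oxidation progress curve (A420 vs time) has a lag, an
approximately linear phase, and saturation as substrate depletes. The linear
phase is isolated by exhaustive window search: among all contiguous windows of
at least `min_points` (default 10) reads, take the longest whose ordinary
least-squares fit reaches `r2_min` (default 0.999), breaking ties by earliest
start. This generalizes "trim points from both ends until R² ≥ 0.999": every
such trimming is a window the search considers, and the result is
deterministic and independent of trimming order. Windows with constant
response are flagged `flat` (slope 0, R² defined as 1); when no window
qualifies the best `min_points` window is reported with `no_linear_window`
and excluded from unit conversion. The scan is vectorized with prefix sums on
globally centred data; the test suite checks it against an independently
coded brute-force search on 1,000 traces.

Slopes convert to enzyme Units (µmol oxidized ABTS/min) by Beer–Lambert:

    activity_U = slope / (ε · l) · V · 10⁶ · dilution

with ε = 36,000 M⁻¹cm⁻¹ (oxidized ABTS at 420 nm), path length `l` in cm
(no default — microplate path depends on fill volume, so it must be given),
and reaction volume `V` in litres (default 200 µL). Negative slopes clamp to
zero activity with a warning. Optional blank-well mean-slope subtraction is
applied before conversion.

## Hit calling

Primary hits are strains whose single-pass activity strictly exceeds
`median + 3 · MAD` over the whole screened library, with
`MAD = 1.4826 · median(|xᵢ − median|)` (the 1.4826 factor makes the MAD a
consistent estimator of σ under normality). The strict inequality means a
degenerate library (MAD 0) calls nothing rather than everything. Secondary
screens confirm candidates against the reference strain with one-sided Welch
t-tests on replicate activities (α = 0.05, uncorrected by default to mirror
the screening usage; BH available). Dual-enzyme results are combined into
per-strain flags (`both`/`a_only`/`b_only`/`neither`) plus the Pearson
correlation of mean activities across candidates.

## Pan-genome enrichment

Strains × ORFs presence/absence calls are first reduced to ORFs that differ
between at least one hit strain and the reference genome (the core genome is
uninformative for this contrast). Each retained ORF is tested with a
two-sided Fisher exact test of presence among hit strains versus the rest of
the library. The test enumerates the hypergeometric support in exact integer
arithmetic (numerators over the common denominator C(n, c₁)), summing tables
whose probability does not exceed the observed table's — so ties are detected
exactly, with no floating-point tolerance. `scipy.stats.fisher_exact` agrees
but costs ~230 µs per call, too slow for exhaustive verification sweeps;
the integer version is checked against both scipy and an independent float
enumeration on every 2×2 table with total ≤ 60.

ORFs are classed `enriched`/`depleted` at α = 0.05 (uncorrected by default,
as in the screening literature this follows; BH optional). A depleted ORF
linked by a homology pair at ≥ 73% amino-acid identity (the observed range of
such pan-genome homolog pairs is roughly 73–99%) to an *enriched* ORF is
reclassified `compensated` — the strain lost one copy but carries a working
substitute; the highest-identity enriched homolog is recorded.

## Phylogeny

Neighbour joining with the standard Q criterion and Studier–Keppler distance
update. Determinism details are pinned: work proceeds in canonical (sorted)
label order, Q ties resolve to the lexicographically smallest pair of
canonical subtree labels (a subtree's canonical label is its smallest leaf
name), children attach in canonical order, and negative branch-length
estimates clamp to zero with a warning. On additive matrices the generating
tree is recovered exactly (verified on 200 random trees of 4–16 taxa).
Rooting places the root at the midpoint of the outgroup's pendant edge,
conserving total branch length. Trees are `skbio.TreeNode` objects serialized
as Newick; serialization is a fixpoint.

## qPCR

Technical replicates are averaged on the Ct scale;
ΔCt = Ct(target) − Ct(reference gene) per strain cancels RNA-input
differences; ΔΔCt subtracts the calibrator strain; relative level is
`efficiency^(−ΔΔCt)` (default efficiency 2 = perfect doubling). The worked
case — calibrator (22, 18), sample (20, 18) — gives exactly 4.0. Activity per
unit mRNA is rescaled so the calibrator is 1, making it invariant to a common
change of activity units.

## Proteomics

- **Replicate QC.** A sample's pairwise R² with another sample is the squared
  Pearson correlation of log₁₀ intensities over mutually observed proteins. A
  sample is excluded iff it falls below 0.85 against *every* other replicate
  of its strain. When a strain's only two replicates are mutually discordant,
  the one with the lower median R² against all other samples is dropped, so
  no strain is emptied by QC.
- **Normalization.** Median scaling: each sample is divided by its observed
  median and multiplied by the mean of the per-sample medians. Idempotent;
  missing cells untouched.
- **Imputation.** DIA missingness is left-censored (low-abundance proteins
  drop out), so missing cells are drawn from Normal(µ, σ) with µ the sample's
  5% observed quantile and σ the standard deviation of the bottom decile,
  halving σ until all draws are positive. Samples with < 20 observed values
  fall back to the global quantile with a warning. Seeded and reproducible;
  observed values never change.
- **Differential abundance.** Welch t-tests per protein on log₂ intensities
  of the imputed matrix, strain vs reference; BH q-values reported; a protein
  is `up`/`down` when |log₂FC| ≥ 1 and p ≤ 0.05 (q under `strict_bh`).
- **Recurrence.** Proteins called in the same direction in at least
  ⌈0.5 · n_strains⌉ strains are recurrent; direction conflicts are excluded
  and reported.
- **CV profiles.** Per-protein sd/mean on the linear scale over a replicate
  group (≥ 2 observations), summarized by the median. With the reference
  strain deeply replicated (14 technical runs of one lysate, 7 biological
  cultures), the synthetic generator reproduces the target ~8% technical /
  ~22% biological medians.

## Synthetic data and default parameters

All generators draw from `numpy.random.SeedSequence(seed, spawn_key=(stage,))`
substreams, so each stage regenerates independently and every output is
byte-reproducible from one seed. Problem sizes below are the package's own
defaults for a realistic workload, chosen once up front.

- **Screen** (600 strains, 30 planted 2× producers): strain activities are
  log-normal around 2 × 10⁻⁴ U with CV 0.15; each well's progress curve is a
  lag (5 min) plus exponential saturation whose initial slope encodes the
  activity via Beer–Lambert and whose plateau is the absorbance equivalent of
  the available substrate (1 mM → 36 AU at 1 cm). 61 reads at 1/min; one
  reference well (A1) per 95-sample plate.
- **Read noise 0.002 AU.** Chosen by a feasibility argument, not tuning: at
  the assay's ~0.036 AU/min slopes, a 10-point window cannot reach R² ≥ 0.999
  if the read noise is 0.01 AU — the stated trimming criterion itself pins
  plate-reader noise at the few-mAU scale typical of modern readers.
- **Secondary screen**: replicate CV 0.22 (biological scale); enzyme B gets
  its own planted producers (one third of candidates) plus weak log-scale
  coupling (ρ = 0.25) to enzyme A, reproducing the empirically weak
  inter-enzyme correlation.
- **Pan-genome** (500 ORFs): planted enriched ORFs are absent from the
  reference and present in 90% of hits vs 15% elsewhere; depleted ORFs are
  present in the reference and 5% of hits vs 75% elsewhere; 70% of background
  ORFs are core (present everywhere, removed by the variable-ORF pre-filter)
  and the rest i.i.d. Bernoulli(0.3). Compensated pairs get identities
  uniform on [0.73, 0.99].
- **Proteomes** (2,000 proteins, 20 strains): log-normal base abundances;
  multiplicative technical (CV 0.08) and biological (CV 0.22) noise; the
  reference strain carries 7 biological + 14 technical replicates; planted
  ±1.5 log₂ fold changes in 60% of strains feed the recurrence filter;
  missingness is logistic in log₂ intensity (left-censoring).
- **qPCR**: per-strain RNA-input offsets hit both genes equally (cancelled by
  ΔCt); Ct noise sd 0.1.

## Limitations

- The exhaustive-window linear fit is O(n²) per trace — negligible for plate
  reads (≤ hundreds of points), not meant for high-frequency sensor data.
- Fisher enumeration is exact but per-table; at margins far beyond screening
  scale (thousands) a normal approximation would be preferable.
- Neighbour joining is the plain O(n³) algorithm, fine for hundreds of taxa.
- The published-study reproduction (`laccscreen.study`) requires the original
  replicate-level supplementary tables, which are not redistributable here;
  the corresponding test documents the expected format and fails until
  `data/study/` is populated.
- Uncorrected α = 0.05 defaults mirror the screening workflow being modelled;
  for confirmatory analyses switch the `correct`/`strict_bh` options on.
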