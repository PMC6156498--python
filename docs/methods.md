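# Methods

This note documents the models and procedures implemented in `mitodel`, the
choices made where the underlying experimental design left them open, and
what the synthetic-data world does and does not establish.

## 1. Stochastic mtDNA turnover and clonal expansion (`dynamics`)

### Model

Each somatic cell holds a population of mtDNA molecules, wild type (wt) and
deletion-bearing (mut), maintained by relaxed replication: molecules are
degraded continuously at rate ln2/t½ per molecule and the cell replicates
surviving molecules — templates drawn uniformly at random with replacement —
back to its copy-number target N (immediate-restore control). A replication
from a wt template yields a mutant with probability μ; mutant templates breed
true. Deletions are selectively neutral, so the intracellular mutant
fraction *f* is a martingale with drift variance ≈ 2·(ln2/t½)·f(1−f)/N per
unit time; clonal expansion is a first-passage problem of this drift.

A worm is 959 independent cells. Development starts from a single zygote
with 25,000 molecules and performs ⌈log₂ 959⌉ = 10 synchronous division
rounds over 3 days, partitioning each cell's molecules binomially between
daughters; between rounds the worm-wide copy number is replicated up a linear
ramp to 300,000 (each replication mutating with probability μ), cells are
pruned uniformly at random to exactly 959, and the total is topped up to
300,000 (≈ 313 copies/cell). The true *C. elegans* lineage is invariant and
asynchronous; synchronous-division-plus-pruning is a deliberate
simplification that preserves copy-number bookkeeping and the neutrality of
drift, not lineage identity.

### Engines and validation

The default engine is a discrete-time binomial stepper (per step: binomial
deaths per class, then multinomial-style replication of the deficit). The
step is distributionally matched to a Moran-type continuous-time process; an
exact event-driven Gillespie implementation (`gillespie_cell`) of the same
birth–death–mutation process is bundled, and the test suite verifies, on
small populations: the neutral-drift martingale, the 1/N fixation
probability of a single neutral mutant, agreement of mean-fraction
trajectories at multiple checkpoints, and agreement of single-cell
first-passage means. Halving the default time step (0.25 d) moves full-scale
first-passage means by ≲ 4% (within Monte Carlo error).

### Parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| μ | 2×10⁻⁴ / replication | de novo deletion probability; an extreme upper bound (~3,000× the measured rate of the human "common deletion") chosen to make clonal expansion as easy as possible |
| t½ | 3–21 d grid; 12 d best estimate | mtDNA half-life, the drift clock; bounded by UV/EtBr lesion kinetics |
| N per cell | 313 | 300,000 copies / 959 cells |
| threshold | 0.60 | intracellular mutant fraction of biochemical compromise |
| dt | 0.25 d (must be ≤ t½/6) | stepper resolution |
| egg copies | 25,000 | zygote mtDNA content |

Cells whose mtDNA goes extinct under turnover (vanishingly rare at N ≈ 313)
are replenished as wild type by default; an "extinct" mode exists for
sensitivity analysis. Age zero is hatching; development occupies ages 0–3 d.

### First passage

`first_passage_time` reports the age at which max-over-cells *f* first
reaches the threshold, per worm, with capped worms reported explicitly (never
silently dropped). With the defaults this gives mean ≈ 2.8 years at
t½ = 12 d and ≈ 0.72 years at t½ = 3 d (recomputed by
`scripts/acceptance.py`). Both are far beyond the 27-day maximum lifespan —
the headline qualitative conclusion — but they sit a factor ~1.6–1.9 below
previously reported estimates for this system (4.8 y and 1.37 y). The
developmental sub-model behind those estimates (egg copy number, division
schedule, copy-number control law) is not specified in enough detail to
reproduce exactly; with mutation active during development, ~150 standing
singleton mutant molecules exist at hatch, and together with the specific
control law this shifts absolute first-passage times within a factor ~2
while leaving the orders of magnitude and all parameter orderings intact.
Note that at t½ = 3 d the simulated mean (~272 d) is essentially *at* the
10× max-lifespan mark rather than comfortably above it, so that hard
inequality is parameterization-sensitive at the fastest turnover.

## 2. Random mutation capture simulation and inversion (`capture`)

### Sampling chain

One capture experiment is modeled exactly as draws without replacement:
homogenate (n_worms × 300,000 copies; default 5,000 worms) → extraction at
configurable efficiency (default 1.0; no recovery figure is available) →
working stock (default 236 × 10,000 molecules) → sequential plating of
10,000 molecules into each of 236 wells. A well amplifies iff it contains
≥ 1 molecule whose deletion is amplifiable by that well's pair, then optional
false-negative/false-positive flips (defaults 0). Multiple deletions in one
well still produce one amplified well (binary fluorescence readout); the
sequenced product is taken to be the amplifiable deletion with the shortest
mutant amplicon (PCR favors short products) — needed when generating
synthetic detection tables, and an assumption the real assay does not pin
down.

Two implementation notes. (i) numpy's hypergeometric sampler rejects
populations ≥ 10⁹, which the pooled homogenate exceeds; such draws use an
exact windowed inverse-pmf sampler (log-pmf via `gammaln` on a ±12 SD window
around the mode; truncated mass < 10⁻³⁰). (ii) The calibration loop uses an
aggregated sampler that exploits two exact identities — nested uniform
subsampling collapses to a single hypergeometric draw, and sporadic mutant
molecules are exchangeable, so each molecule in well *j* is independently
amplifiable with the pair's spectrum detectability q_j. A KS test in the
suite confirms the aggregated and species-resolved chains agree in
distribution.

### Calibration and inversion

For each virtual mutant fraction on a grid (default 16 log-spaced points,
10⁻⁶–2×10⁻³), the whole in-silico experiment is repeated 1,000 times and the
empirical pmf of amplified-well counts stored. Mutant molecules follow a
sporadic spectrum prior: uniform independent breakpoints in the scanned
window, length ≥ 500 bp — the minimal model consistent with the detectability
simulation; an empirical spectrum can be substituted. Inversion maximizes
the product of add-half-smoothed empirical count probabilities over the
grid, refines the argmax by quadratic interpolation of the log-likelihood in
log₁₀ f, and builds the 95% CI by tail inversion at the observed median
count (lowest f whose upper tail at the median reaches 2.5%, highest f whose
lower tail does). CI calibration is verified by simulation (coverage ≥ 90%
at a known generating fraction). Burdens are fractions × 300,000 per worm,
÷ 959 per cell; the age trend is tested by OLS of fraction on age.

### Known limitation: absolute burdens depend on panel geometry

The inverted burden scales inversely with the mean number of panel pairs
able to amplify a random deletion (the per-molecule detectability
q̄ = mean-amplifying-pairs / 236). The real primer coordinates are not
published; the synthetic layout reproduces the panel's two documented
aggregate properties (236 valid pairs; ≥ 95% detection coverage of ≥ 500 bp
deletions) but its multiplicity at the default L_max = 1,000 bp is ≈ 2.9
amplifying pairs per deletion, whereas reproducing the previously reported
absolute burden (~82 molecules/worm from ~11 amplified wells) requires ≈ 4.0 —
reached by this layout at L_max ≈ 1,200 bp. With the defaults, the
acceptance suite measures a cross-age mean burden of ~111 molecules/worm
(~0.12/cell): same order, ~35% high, and the corresponding acceptance checks
are deliberately left failing rather than retuning L_max post hoc. Relative
statements (no significant age trend at realistic uncertainty; burden ≪
threshold) are insensitive to this scale factor, though note that exactly
linear input counts (9.20/11.00/13.00 with only three ages) make the 3-point
OLS trend p-value essentially a measure of the calibration curve's local
curvature, not of biological signal.

## 3. Primer panel geometry (`panel`)

A pair (forward F, reverse R; 1-based closed template coordinates, reverse
primers stored by footprint) detects deletion [b5, b3] iff F.end < b5,
b3 < R.start, and wt_amplicon − deletion length ≤ L_max. Panels enumerate
all F×R combinations with the forward upstream whose wild-type amplicon
exceeds L_max (wild type must never amplify). L_max defaults to 1,000 bp
(75 s combined annealing/extension supports ~1 kb) but is configurable, and
coverage is always reported as a function of L_max because the experimental
value is not stated. Coverage Monte Carlo samples two i.i.d. uniform integer
breakpoints in [1,800, 10,800] (the minimal reading of "random breakpoints"),
orders them, filters at min length 500 bp, and reports the detected fraction
with its binomial SE.

The canonical synthetic layout places 12 forward primer starts evenly on
[1,800, 9,375] and 36 reverse primer ends evenly on [3,150, 10,800] (20-mers);
under the validity rule at L_max = 1,000 this yields exactly 236 pairs with
99.1% coverage. The spacing was chosen once, from the documented pair count
and coverage, before any burden calculation.

## 4. Breakpoint direct repeats (`genome`)

Junctional repeats are scored on the plus strand, perfect matches only, at
the two canonical placements of the representation ambiguity: start-anchored
(ref[b5..b5+r−1] = ref[b3+1..b3+r]) and end-anchored
(ref[b5−r..b5−1] = ref[b3−r+1..b3]). The maximal r in [min_len, max_len]
is reported, ties broken toward start-anchored; max_len defaults to 30 bp (a
package choice; the scanned region never wraps the circular origin, but
wrap-around is supported). Imperfect/degenerate repeats are out of scope.

## 5. Clonality statistics (`clonality`)

Deletion identity is exact (b5, b3) equality (junction micro-ambiguity under
flanking repeats can shift coordinates; a tolerance flag exists, default 0).
Within-cohort multiplicity counts detections of each unique junction across
one cohort's replicate assays; between-cohort multiplicity counts cohorts
per junction. The discrimination logic: a clonally expanded deletion is
abundant in its cohort's extract and recurs across that cohort's replicates,
while a hotspot deletion recurs across independent cohorts. `sporadic_null`
makes this quantitative — a simulation extension labeled as such in its
output: it replays the full detection experiment with every mutant molecule
a distinct single-copy spectrum draw, so within-cohort repeats can arise only
from copy number, not chance, and reports Monte Carlo p-values.

## 6. Lesion decay and half-life bounds (`decay`)

Lesions per long fragment = −ln of treated/control relative amplification
(perfect doubling per cycle assumed; efficiency configurable), the Poisson
zero-class estimator. First-order decay is fit by least squares on
ln(lesions) vs time — matching the 2–6-point series this assay produces —
with non-positive values excluded and counted; k within 2 SE of zero is
flagged "no detectable decay" and contributes only a lower bound on t½
(window × ln2 / ln resolvable-fold-change) to the admissible half-life
envelope.

## 7. The synthetic world (`synth`)

Generators are deterministic under (spec, seed) and ship truth manifests.
The reference is i.i.d. uniform A/C/G/T at the real mitochondrial genome
length (13,794 bp) with exact direct repeats planted at junction-compatible
placements — so repeat detection is exercised with known answers, but the
sequence has none of the real genome's base composition, gene structure, or
AT-rich region. Cohort detection tables are produced by running the actual
capture simulator on homogenates whose mutant mass is split between a single
expanded clone (`clonal_weight`) and sporadic singletons; an optional flag
models the ~30% age-dependent copy-number decline. The deterministic
worked-example table (`worked_example_detections`) is constructed to the
documented summary marginals of the emulated experiment — 312 detections /
266 unique junctions over 11 cohorts; a 10-replicate day-10 cohort with
148/124/9 and 92.74% seen once; nine between-cohort junctions (eight in two
cohorts, one in three); DRs ≥ 8 bp planted at 7/9 within- and 6/9
between-cohort repeated junctions — with per-junction identities generated,
not measured; the placement of the 12 duplicate events not pinned down by
those marginals (extra within-cohort repeats in day-4 cohorts) is a
construction choice. A green test on this twin establishes that the
tabulators are exact, not that the biology was re-measured.

## 8. Reproducibility

Every stochastic operation takes an explicit integer seed; CLI runs write
JSON metadata sidecars (seed, package version, input checksums, wall time),
and result files are bit-for-bit reproducible under identical config + seed
(asserted in the suite).
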