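# Methods

## The statistic

The package analyses binary species × sample incidence matrices derived
from count data (presence = count ≥ 1 by default; the threshold is
exposed).  For an unordered species pair *(i, j)* with row sums *r_i*,
*r_j* and *S_ij* jointly occupied samples, the checkerboard-unit count is
`(r_i − S_ij)(r_j − S_ij)`; the matrix statistic is the sum over all
unordered pairs, with unordered sample pairs counted once.  This equals a
direct enumeration of 1-0/0-1 2×2 submatrices over all species-pair ×
sample-pair combinations, which the package also implements
(`checkerboard_units_bruteforce`) and tests against, both on random
matrices and exhaustively on all binary 4×4 matrices.  The count is not
divided by matrix size (no C-score): raw units from per-group sub-matrices
are summed, which a normalized score would not permit.

Zero rows and zero columns contribute nothing to the statistic and are
invariant under margin-preserving randomization.  Consequently, empty
samples are *retained* (keeping N consistent with the survey design) while
species absent from a group are *dropped* from that group's sub-matrix
before randomization — an output-equivalent optimization asserted in the
tests.

## The null model

The null hypothesis is random co-occurrence conditional on both marginal
sums: each species keeps its number of occurrences, each sample its
richness.  Null matrices are sampled with the curveball algorithm (random
row pairs trade random subsets of the columns held by exactly one of
them), restarting from the observed matrix for every draw.  Steps per draw
default to `max(50, 5 × n_rows)`: five trades per species row is a safety
margin beyond the empirical mixing time of curveball trade chains, and the
floor of 50 keeps very small matrices (where a handful of trades can
retain start-state bias) fully mixed.  Uniformity is verified empirically:
on every margin class small enough to enumerate exhaustively
(backtracking enumerator, also used to detect Gale–Ryser-infeasible
margins), chi-square tests on thousands of draws do not reject uniformity
at α = 0.01, for both curveball and the trial-swap alternative.
Trial swap (classic 2×2 checkerboard flips) converges far more slowly per
attempt, so its step default is `15 × n_rows × n_cols`; it exists to
cross-check the curveball null, and the two algorithms' null means agree
within Monte-Carlo error, as does the null mean obtained from vegan's
quasiswap in R on a fixture matrix.  "quasiswap" is accepted as an alias
for curveball: the contract (uniform sampling of the fixed–fixed margin
class) is identical.  Matrices with fewer than two species or samples, or
alone in their margin class, pass through unchanged — such sub-matrices
are common in sparse per-tree data.

All randomness flows through explicit integer seeds or numpy Generators;
per-group and per-repeat seeds are spawned from the master seed via
`SeedSequence`, so every result (including the null draws themselves) is
exactly reproducible from its seed, and groups are statistically
independent.

## The two tests

**Within-group test.**  Observed statistic: summed CU over per-group
sub-matrices.  Each null replicate randomizes every group independently
(never across group boundaries) and re-sums.  The p-value is upper-tail
Monte-Carlo with add-one correction, `p = (1 + #{null ≥ obs}) / (1 +
n_null)` — never exactly zero, monotone in the observed count.  The
default n_null is 1,000.

**Between-group test.**  Virtual groups are assembled so that the test
for between-group structure has exactly the sample size and matrix
structure of the within-group test: each virtual group holds one sample
from each of `samples_per_virtual` distinct real groups.  Two
constructions are provided and reported in the output metadata:

* *independent* (default): every virtual group draws its real groups and
  samples independently; a sample may serve several virtual groups.  This
  is the weaker assumption about how the original virtual trees were
  built.
* *partition*: every sample is used exactly once
  (`n_virtual × samples_per_virtual` must equal the total sample count).
  Implemented as random sequential assignment with restart; the proposal
  is capacity-aware — virtual groups whose remaining capacity equals the
  number of unplaced real groups are forced, and otherwise groups are
  chosen with probability proportional to remaining capacity — because a
  uniform proposal dead-ends almost surely on the 20 × 8 design.

The within-group machinery is then run on the virtual grouping (species
universes recomputed per virtual group), the construction is repeated 10
times by default, and the final p-value is the arithmetic mean of the
repeat p-values.  The reported histogram (observed count and null draws)
belongs to the first repeat, mirroring how one example construction is
plotted.

**Calibration caveat.**  The within-group test is well calibrated: on
independence-null communities its rejection rate at α = 0.05 is ≈ 0.05.
The between-group test's p-value *averaging* makes it conservative as an
α-level test: under the null each repeat's p-value is approximately
uniform (verified by simulation), so the mean of ten weakly correlated
repeat p-values concentrates near 0.5 and almost never falls below 0.05.
Averaging stabilizes the p-value against the randomness of virtual-group
construction — the procedure's stated purpose — at the cost of nominal
type-I calibration; users needing a calibrated between-scale test should
inspect the per-repeat p-values (retained in the result) rather than the
mean.  This behaviour is measured, not assumed: the acceptance protocol
reports both rates.

## The synthetic generator

`generate_mosaic` emulates a balanced canopy survey: `n_groups` trees ×
`samples_per_group` samples (defaults 20 × 8, the bait design; 20 trays
for fogging), a pool of `n_dominants` (5) potentially territorial species
and `n_subordinates` (40) rare tolerated species.  Steps, in order: each
tree gets a uniformly chosen resident dominant; each non-resident dominant
is barred from a tree with probability `exclusion` (1 = full mosaic, 0 =
independence); allowed dominants occur per sample as independent
Bernoulli(`dominant_occupancy` = 0.8) flips; subordinates occur at
`subordinate_occupancy` = 0.05, thinned with probability `suppression`
(default 0) in samples holding a dominant; counts for present occurrences
are zero-truncated negative binomial (dominants mean 10, subordinates mean
2, dispersion 0.5) — the strong right skew of social-insect abundance
data.  Exclusion acts on tree-level access, matching the concept of
whole-crown territories; trees have no spatial arrangement (they are
treated as exchangeable, as widely spaced crowns).

What the generator does *not* emulate: within-tree spatial structure,
species-specific detection differences between baiting and fogging,
temporal autocorrelation between day and night surveys, and between-tree
habitat heterogeneity.  Two consequences matter for interpreting the
simulation studies.  First, because species are placed independently
*within* trees (at suppression = 0), the within-tree null is true by
construction at every exclusion level — conditional on its margins each
sub-matrix is exactly uniform on its margin class — so within-tree
detection power on generator output equals α unless `suppression > 0`,
which is the generator's only source of genuine within-tree structure.
Second, between-tree signal at the defaults comes solely from dominant
turnover: with dominant occupancy 0.8 and rare subordinates the observed
summed CU sits only ≈ 2 standard deviations above the null mean, and the
conservative p-averaging brings between-test power at full exclusion to
roughly 0.1–0.2 rather than near 1 (with `dominant_occupancy = 1` the
same test rejects essentially always).  Passing calibration and
monotonicity tests on this generator therefore demonstrates correctness
of the machinery, not field-level effect sizes; real communities carry
additional between-tree heterogeneity (subordinate turnover, richness
differences) that the generator deliberately omits.

`generate_null_community` is the pure independence null (every cell an
independent Bernoulli presence, abundance 1) used for type-I studies.

## Problem sizes and numerical choices

* Simulation studies use 200 null matrices per test (p-value resolution
  1/201 ≈ 0.005), 500 datasets for type-I rates and 100 per grid point for
  power curves; these sizes put Monte-Carlo error well inside the decision
  bands used in the tests.
* Monte-Carlo p-values use the add-one correction, chosen over the raw
  proportion to avoid p = 0 — standard for permutation tests.
* Dominance ties are broken by dataset-wide abundance, then lexicographic
  species id, and always flagged; turnover counts exclude groups empty in
  either summary.  Mean per-sample richness includes empty samples.
* Sample, group and species orderings are lexicographic everywhere;
  results are independent of input row order.
* 31-bit kernel seeds are derived from `SeedSequence` state; the numba
  kernels bit-pack rows into uint64 words, so matrices up to 64 samples
  use single-word operations (wider matrices use multiple words
  transparently).

## Known limitations

* The between-scale averaged p-value is conservative (see above); it is
  reported faithfully rather than recalibrated.
* The partition-mode virtual grouping samples feasible partitions through
  a weighted sequential construction, which is not exactly uniform over
  all feasible partitions.
* `enumerate_margin_class` is guarded to tiny matrices (≤ 25 cells); it is
  an oracle for testing, not an analysis path.
* Abundances play no role in the segregation tests (presence/absence
  only); they exist for dominance summaries and realistic data shapes.
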