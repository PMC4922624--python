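# Methods

This note documents the models, conventions and numerical choices behind
`cnvmap`, in the order the pipeline runs.

## Coordinates and input conventions

All intervals are held internally as 0-based half-open `[start, end)`;
lengths and overlaps are plain differences. PennCNV `rawcnv` files are
1-based inclusive and converted at the I/O boundary; BED input/output is
natively 0-based half-open and passes through unchanged. Chromosome
names are normalized by stripping a `chr` prefix; comparison is
case-sensitive afterwards. Thousands separators in rawcnv numeric fields
are stripped. A rawcnv `length=` field disagreeing with the coordinates
by more than 1 bp produces a warning and the coordinates win. A record
with `cn=2` is rejected: a call is by definition a deviation from the
diploid state.

## Call-level quality control

Three filters, with removal attributed to exactly one reason in the
precedence sample > chromosome > length:

* samples with **more than 150 calls** are dropped entirely — an excess
  of calls indicates a low-quality array whose false positives would
  concatenate into inflated regions. The threshold is applied to the
  *pre-filter* count, as array quality is a property of the sample, not
  of the calls that happen to survive other filters;
* calls on non-autosomes are removed (hemizygous sex chromosomes break
  the diploid baseline);
* calls **shorter than 5 kb** are removed; a call of exactly 5,000 bp is
  retained (the exclusion is strict).

`filter_calls` is idempotent and never modifies surviving records.

## CNVR compilation

Losses (CN < 2) and gains (CN > 2) are processed separately. On each
chromosome, calls overlapping by at least one base are clustered
transitively (touching intervals do not cluster). Within a cluster the
per-base density is

    density(b) = (# member calls covering b) / (# calls in the cluster)

and bases with density below the recurrence threshold (default 0.1) are
trimmed; each maximal surviving run becomes a region, so a cluster may
split. The denominator is the cluster's call count: the trimming is a
statement about support *within* the region, which is well defined
without sample weights and reproduces the intended removal of
thinly-supported tails. (The alternative denominator — population size —
is exposed only through the recurrence parameter itself: with
recurrence `r` and cluster size `k`, density `r` relative to the cluster
equals density `r·k/N` relative to a population of `N`.) Trimming is
computed on interval breakpoints, never per-base arrays, so it is exact
at any scale; a per-base oracle is used in the tests to verify
equivalence.

Overlapping gain and loss regions are then merged transitively into
"both" regions spanning the hull of the chain. Same-type regions can
never overlap by construction, so every merge is cross-type.

Each call is then assigned to the single final region it overlaps most
(leftmost on ties). Membership by bare overlap would let one long call
belong to both fragments of a split cluster; unique assignment keeps
membership a partition, which the frequency bookkeeping and the
fixed-state check rely on. Region frequency is the number of distinct
carrier samples among members divided by the population size — the
population may exceed the number of samples contributing calls.
Frequencies are computed on the final (trimmed, merged) regions.

Classification thresholds: *polymorphic* means frequency strictly
greater than 1%; the *fixed-state* artifact flag requires frequency
above 75% **and** one CN state accounting for strictly more than 95% of
member calls. Region ids are assigned in (chromosome order, start)
order after merging.

## Overlap statistics

Two measures: the number of query regions overlapping at least one
target base (directional), and the total bp of the intersection of the
two sets' base unions (symmetric; overlapping query regions never
double-count a base). Random region sets preserve each query region's
length and chromosome and draw the start uniformly over valid
placements; regions longer than 1 Mb are excluded from both the
observed measure and every permutation, so the two are comparable.
Random regions may overlap each other (a rejection-sampling
non-overlapping mode exists but is off by default, since the observed
region set itself is typed-disjoint but the null model does not need
that constraint).

The empirical p-value is the add-one estimator `(k + 1)/(N + 1)` with
ties counted toward k, so p is never 0 and "p < 0.001 at N = 1000"
corresponds to no permutation as extreme as the observation.
`alternative="auto"` chooses the side from the sign of
observed − null mean; no doubling is applied (one-sided inference).

Cross-study matching uses mutual overlap: two regions are the same event
only if the shared bases exceed 70% of *each* region's length.

## CN-state association scan

The scan regresses the phenotype on the integer copy number (0–4) at
each variable probe — the simplest model consistent with a per-probe
quantitative-trait CNP analysis, treating dosage as additive. CN is not
factorized into genotype classes; a permutation p-value (phenotype
shuffling, add-one estimator on |β|) is available as an option.
Default thresholds:

| parameter | default | meaning |
|---|---|---|
| `min_dev` | 0.05 | min fraction of samples deviating from 2n for a probe to enter |
| `identity_frac` | 0.95 | min fraction of samples with identical CN at consecutive probes to chain |
| `window_bp` | 450,000 | neighbor-gene window on each side of a segment |

"Consecutive" means consecutive in the *selected* probe list on one
chromosome: intervening invariant probes do not break a segment, since
selection precedes chaining. Chaining is pairwise (each probe against
its predecessor), greedy left to right. The representative probe is the
member with the smallest p-value, leftmost on ties; per-state animal
counts are taken at the representative probe over phenotyped samples.
Samples missing from the phenotype table are excluded from the
regression pairwise but still count toward deviation and identity
fractions (the cohort is larger than the phenotyped subset). A constant
CN row or fewer than 3 usable samples yields a flagged degenerate
result (β = 0, p = 1) rather than an error.

Multiple testing uses Benjamini–Hochberg step-up adjusted p-values
(via statsmodels), reported at the 0.05 and 0.10 thresholds. Probes of
one sample covered by two overlapping calls are an error: a probe's
copy number is then undefined and indicates invalid upstream calling.

The scan is exposed statsmodels-style: `CNVStateGWAS(...)` holds data
and parameters, `.fit()` returns a `CNVStateGWASResults` carrying the
segment table, per-probe statistics, diagnostics and `summary()`.

## qPCR copy-number estimation

Cycle thresholds are corrected as `ct · log2(E)` with the primer's
amplification efficiency E ∈ (1, 2]: the corrected value is the number
of perfect doublings equivalent to the observed cycles, exact for E = 2
and shrinking cycles for weaker primers. The published phrasing of the
correction is ambiguous; this form was chosen because it makes the
2-based exponentiation downstream exact, and it is isolated in one
function so an alternative (e.g. `E^ΔΔCt`-style) can be swapped in.
Triplicates are aggregated by the arithmetic mean of corrected values;
an optional outlier rule (drop a replicate deviating > 1 cycle from the
median) is off by default. One efficiency applies to a record's target
and control wells (a primer-pair mean), which makes ΔΔCt exactly
invariant under a global Ct shift.

ΔCt = mean corrected target − mean corrected control;
ΔΔCt = ΔCt − (mean ΔCt over array-diploid samples for the primer);
NR = 2·2^(−ΔΔCt). Categories follow geometric-mean boundaries:
category n for √(n(n−1)) < NR ≤ √(n(n+1)), n = 1..4; NR > √20 is 5n;
no amplification is 0n. A tie exactly on a boundary goes to the lower
state — a deterministic rule the published scheme leaves open. The
analysis fails loudly if a primer has no array-diploid sample to anchor
the reference.

Concordance compares per-sample CNV *types* (loss/normal/gain): a
sample agrees when both platforms show the same non-normal type, or
when both are normal. Normal/normal agreement counts toward the
per-region concordance percentage but not toward validation, which
requires at least one sample sharing a loss or gain; both percentage
variants (with and without normal/normal in the numerator) are
reported.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
at desk scale. Defaults:

| parameter | default | rationale |
|---|---|---|
| animals | 100 | enough for 1%-frequency classes to be populated |
| genome | 5 × 10 Mb | tens of seconds end-to-end |
| probe spacing | 3.2 kb | ~770k-probe HD chip on a 2.5 Gb genome |
| CNV loci | 40, lengths log-uniform 5–500 kb | matches the call-length filter and observed CNVR scales |
| locus frequencies | uniform 0.01–0.6 | spans rare to common polymorphisms |
| gain fraction | 0.4 | gains are the minority of regions in cattle-array maps |
| boundary jitter | SD 3.2 kb, snapped to the grid | one probe spacing of boundary uncertainty |
| false positives | Poisson(2)/animal, 5–50 kb | short spurious calls, mostly removed by QC |
| causal loci | 3, β = 0.8/−0.6/0.5 per copy | detectable but not trivial at n = 100–200 |
| phenotype | y = μ + Σ β_l(CN_l − 2) + N(0, 1) | additive dosage model |
| qPCR | base Ct 25, E = 1.9, noise 0.1 cycles, triplicates | typical SYBR assay |

Loci are placed without overlap (one probe spacing apart); a dedicated
flag plants one gain/loss pair with partial overlap to exercise
"both"-type regions. Carriers are Bernoulli per locus; a carrier is one
copy off (CN 1 or 3) with probability 0.9 and two copies off (0 or 4)
with 0.1. Emitted calls jitter the true boundaries by a grid-snapped
normal; when jitter makes two calls of one animal touch, the later call
is clipped at the earlier one's end, as an HMM caller emitting disjoint
segments would behave. qPCR plates are generated on the corrected-Ct
scale (target = base − log2(CN/2) + noise) and de-corrected by
log2(E), so the analysis recovers CN exactly at zero noise.

Randomness derives from one root seed through per-component
`SeedSequence` children (loci, carriers, calls, phenotype, qPCR), so
outputs are byte-stable and changing one sub-configuration does not
perturb the others.

What the generator does **not** model: linkage disequilibrium between
loci, pedigree/population structure, intensity-level artifacts
(genomic waves, batch effects), chromosome-specific probe density, or
locus-specific qPCR primer behavior. Passing tests therefore show the
*analysis* is correct under its assumptions, not that those assumptions
hold in any particular real cohort — in real data, relatedness alone
can inflate association statistics, and the pipeline deliberately
performs no kinship correction.

## Problem sizes in the tests and acceptance script

The oracle-equivalence suite compares the region compiler with a
per-base reimplementation on 200 random call sets over a 100 kb genome.
Permutation calibration uses a single 10 bp query/target on a 100 bp
chromosome, where the null overlap probability has the closed form
19/91, at N = 5000 permutations. Association calibration uses 1000
independent null probes at n = 200 (type-I error within the exact
binomial 99% interval) and 20 seeded replicates with one causal locus
(β = 0.8·SD, frequency 0.2, n = 200) for power. Depletion/enrichment
power runs 200 loci and 500 genes over 5 × 10 Mb. qPCR checks use
zero-noise plates for exact recovery of states 0–4 and 0.1-cycle noise
for ≥95% accuracy over states 1–3. These sizes were chosen so the
statistical properties under test are sharp at desk scale.

## Known limitations

* The recurrence-trimming denominator is a documented choice (cluster
  call count); other tools may normalize differently, so region
  boundaries need not match any specific external implementation.
* OLS on integer CN ignores genotype-class non-additivity and
  population structure.
* The ΔΔCt efficiency correction form is a convention (see above).
* The CLI's `all` command drives the synthetic workflow; real-data runs
  use the per-stage subcommands with explicit input paths.
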