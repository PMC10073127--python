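# Methods

This note documents the statistical procedure implemented by `cnvburden`,
the assumptions behind the synthetic-data generator, the numerical
choices, and the limits of what the simulation-based tests demonstrate.

## Coordinate model

All intervals are 0-based half-open on opaque chromosome tokens. BED
input needs no conversion; the depth-caller text dialect is declared
1-based fully closed and shifted (start − 1) exactly once, at parse time.
Keeping a single conversion site is what makes the "known pair" fixtures
in the I/O tests meaningful: an off-by-one anywhere downstream would
break footprint conservation, which is asserted in bp.

## Call-level filters

Only the depth-based caller emits quality fields, so only its calls are
filtered; the other callers are used with their default output. A call
is retained iff

* `eval1 < 1e-3` and `eval2 < 1e-3` — the caller's two primary
  significance values for the depth deviation;
* `q0 < 0.5` and `q0 ≠ -1` — at least half the reads in the call region
  map with non-zero quality (−1 is the caller's undefined sentinel and
  always fails);
* for deletions only, `norm_rd < 0.75 · (1 + q0)` — a depth-consistency
  rule: a genuine loss must show depleted normalised read depth even
  after crediting the fraction of unmappable reads. Duplications are
  exempt.

All inequalities are strict, so boundary values are removed. The depth
rule reads "norm_rd" in genome-normalised units (diploid ≈ 1.0); the
factor is exposed as `del_rd_factor`, so a copy-number-unit reading
(threshold 1.5·(1+q0)) is expressible by changing one parameter. The
filter is idempotent and monotone in all three thresholds (property
tests), and never touches coordinates or event types.

## Consensus merging

Within one sample and one event type, two calls are "the same event"
when their reciprocal overlap — `min(shared/len(a), shared/len(b))` —
is strictly greater than 0.5. Reciprocal (two-way) overlap is the
standard criterion in SV merging because one-way overlap would absorb
any small call into an unrelated giant one. Clustering is transitive
(union-find over the overlap graph): a chain a–b–c merges even when a
and c barely overlap. A component's interval is the **union span** of
its members — the union, not the intersection, preserves every member
breakpoint for the segmentation step — and its support is the number of
distinct callers (not calls). Components with support < 2 are dropped;
the secondary cohort, genotyped with the single depth-based caller, uses
a support floor of 1 instead.

## Segmentation and copy states

All consensus start/end positions on a chromosome, pooled across
samples, partition the consensus footprint into atomic regions. The
regions are disjoint, sorted, and cover exactly the union of consensus
intervals (asserted in bp); every region boundary is some consensus
endpoint. Regions covered ≥ 50% by the (internally unioned)
centromere/telomere/segmental-duplication track are removed. No minimum
region length is imposed by default (`min_region_bp = 1`): near-
coincident breakpoints from jittered calls legitimately produce 1-bp
regions.

Each (region, sample) cell is then LOSS, GAIN, NEUTRAL, or CONFLICT
(deletion and duplication consensus both covering it). Because regions
derive from the same consensus set, coverage is all-or-none; a partial
overlap is a consistency error, not a judgement call. The matrix stores
carrier status, not integer copy number: association testing is a 2×2
carrier test, and the simulator plants heterozygous events only, so a
binary state loses nothing there.

## Association

Per region and event class, the 2×2 table counts case/control carriers
vs non-carriers, excluding CONFLICT samples from that region's
denominators. The two-sided Fisher p-value follows the
minimum-likelihood rule — the sum of hypergeometric probabilities, over
all tables with the observed margins, that do not exceed the observed
table's probability — with a relative tie tolerance of 1e-7 to absorb
floating-point ties. The implementation sums `scipy.stats.hypergeom`
probabilities over the support and is memoised on the table (simulated
cohorts repeat the same small tables thousands of times); it is checked
against an exact integer-arithmetic enumeration (`math.comb`, exact ties)
on every table with total ≤ 40 and on random tables with totals to 200,
and against `scipy.stats.fisher_exact`.

The odds ratio is `ad/bc` with a Wald 95% CI on the log scale
(`log OR ± 1.96·√(1/a+1/b+1/c+1/d)`). With any zero cell the
Haldane–Anscombe correction adds 0.5 to every cell first (the default;
`correction="none"` raises instead). The Wald interval was chosen for
closed-form testability; it is anti-conservative for tiny cells, which
is acceptable because selection gates on p-values, never on CI bounds.
Benjamini–Hochberg q-values are attached for reporting but are not used
by any gate: the selection thresholds are deliberately raw p-values.

Losses and gains are tested separately per region; a combined 3-level
test is out of scope. The global burden summary collects ORs of results
with p < 1e-5 per class and compares log-OR distributions with a
two-sided Mann–Whitney test: exact enumeration when both classes have
≤ 10 members and no ties, otherwise the tie-corrected normal
approximation without continuity correction (so identical samples give
p = 1 exactly).

## Multi-cohort selection

A region-event is selected iff primary p < 1e-5; each case batch vs the
shared primary controls has p < 0.05 with the same OR direction; and a
secondary-cohort region matched by reciprocal overlap > 0.5 (the same
rule as call merging, for internal consistency) has p < 0.05 with the
same direction. Direction concordance can be disabled. The per-batch
gate is the weakest reading of requiring the signal in both batches;
both thresholds are exposed.

Breakpoint jitter scatters one true CNV's boundaries over tens of bp, so
a single locus appears as a stack of contiguous atomic regions: a highly
significant core flanked by progressively weaker slivers. Selected
regions of one event type within `locus_gap` (default 1000 bp, chosen
from the jitter geometry — 3 sd of jitter is 60 bp, and slivers are
strictly contiguous) are therefore reported as one locus, with the
minimum-p member as its representative. Selection is monotone in every
threshold: tightening never adds a locus.

## The simulator

Defaults encode the emulated study design:

| parameter | default | meaning |
|---|---|---|
| cohort sizes | 210 + 100 cases / 100 controls primary; 100/100 secondary | two case batches plus an independent validation cohort |
| genome | 2 chromosomes × 5 Mb | desk-scale while exercising multi-chromosome logic |
| planted loci | 3 deletions, 1.2–2 kb | case carrier freq 0.5 vs control 0.15 — a strong common risk deletion (control frequencies of real analogues span roughly 0.1–0.3) |
| background rate | 3 CNVs/sample, log-normal lengths (median 2 kb, σ_log 0.6) | group-independent: a built-in null yielding > 1000 testable background regions per study |
| callers | 5: one depth-based with quality fields + 4 generic | sensitivity 0.9, breakpoint jitter sd 20 bp, 1 false call/sample (Poisson) |
| depth model | DEL norm_rd ~ N(0.5, 0.05), DUP ~ N(1.5, 0.10), truncated at 0 | heterozygous one-copy loss/gain only |
| q0 | Beta(1, 19) | mostly clean mappability; the q0 < 0.5 rule rarely fires on true calls |
| e-values | true calls ≤ 1e-4; false calls large with probability 0.5 | the e-value filter removes about half the depth-caller's false positives |
| repeat track | 5% of each chromosome | telomere stubs at both ends + central centromere block + random segmental-duplication blocks; coverage is exact by trimming the last block; never overlaps planted loci |

Carriers are drawn independently per sample (Bernoulli at the group's
frequency); background events are resampled on overlap with planted loci
or the same sample's events. Everything derives from a single seed via
`numpy.random.SeedSequence` spawning, so identical configs give
byte-identical fixtures; derived stream seeds stay below 2³¹.

For the direction-asymmetry analysis the plant is 6 risk deletions plus
6 protective duplications (case 0.05 vs control 0.30). Six per class is
the smallest symmetric design whose exact rank-sum test can in principle
reach p < 0.05 with margin (with 3 per class the two-sided floor is
2/C(6,3) = 0.1).

What the simulator does **not** emulate: read-level data (depth profiles,
GC waves, split reads), homozygous events and multi-copy amplifications,
caller-specific error correlations (simulated callers err independently,
which flatters consensus calling), linkage between loci, population
structure or batch effects, and sex chromosomes. Passing tests therefore
demonstrate the pipeline's correctness and its statistical behaviour
under the assumed noise model — not calling accuracy on real WGS.

## Problem sizes and determinism

The test suite runs the full 610-sample study end to end (about half a
second per seed once the Fisher cache is warm): locus recovery is
checked over 100 seeds, the type-I error over two pooled null studies
(~3000 tests), and the exact-test oracle over all 135,750 tables with
total ≤ 40. The acceptance script uses 25 recovery seeds. All analysis
outputs, including the on-disk pipeline's TSVs and audit log, are
byte-identical across reruns on the same inputs.

## Known limitations

* Carrier status, not copy number, is the unit of testing; a locus where
  cases carry homozygous and controls heterozygous deletions at equal
  carrier rates would be invisible.
* The Wald CI and the Haldane correction bias the OR toward 1 for sparse
  tables; exact (conditional maximum-likelihood) ORs are not computed.
* Region matching between cohorts is single-best by reciprocal overlap;
  a secondary region legitimately split in two may fail the > 0.5 rule.
* Unknown caller identifiers pass through unfiltered (with a warning) —
  deliberate, so the pipeline is usable with callers it has no rules
  for, but it means a typo in "cnvnator" silently skips filtering.
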