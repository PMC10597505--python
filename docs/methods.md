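# Methods

## Clonal tree model

The simulator represents subclonal structure as a rooted binary tree whose
K leaves are subclones. Each node carries a half-open interval ⊂ [0, 1);
the root owns [0, 1) and the two children of a node partition its interval
exactly, so leaf interval lengths always sum to 1 (enforced to 1e-9).

Growth is by **reverse splitting**: at each step a current leaf is chosen
with probability proportional to (1 − its interval length), normalized
over current leaves; the lone root (weight 0) is split unconditionally.
Small clones therefore keep splitting while large clones are retained,
which amplifies cluster-size contrast. The fraction of the parent
interval given to the left child is drawn from Beta(α, β) with α fixed at
0.5 and β the *Beta splitting variable*; smaller β pushes mass toward
extreme fractions and hence more uneven clone sizes. After the topology
reaches K leaves, each of the 2K − 2 edges receives an i.i.d.
Exponential(rate = 1) branch length (lengths are drawn only after the
topology is complete, so the split sequence is independent of them).

Mutations are placed on edges by a multinomial draw with probabilities
proportional to branch length; cells are placed on leaves by a multinomial
draw with probabilities equal to interval length. Both draws are
conditioned on every category being non-empty, so that the dataset really
contains K distinguishable clusters and every clone has a distinct
genotype.

### Degenerate draws and repair

Reverse splitting produces heavy-tailed interval lengths: at β ≤ 0.2 a
leaf interval of 1e-8 or smaller is common, and an Exponential edge can be
much shorter than 1/M. For such trees the probability that a plain
multinomial draw fills every category is essentially zero, so rejection
sampling alone cannot terminate. The implementation rejection-samples up
to 1000 redraws and then *repairs* the final draw: one unit is moved from
the currently largest category into each empty one. The repair perturbs
at most K − 1 cells (or E − 1 mutations), keeps totals exact, and leaves
the proportional-allocation law untouched whenever rejection succeeds —
which is the typical case for β ≥ 0.5. Genuinely infeasible requests
(N < K cells, or fewer mutations than edges) raise an error instead.

A consequence worth knowing: under reverse splitting with the default
β = 0.2, a typical 8-clone, 500-cell dataset has clone sizes spanning
singletons to hundreds (population SD of sizes ≈ 140 on average). The
cluster-size SD statistic (`cluster_size_sd`) uses the population
convention (divisor K); with K = 8 the sample convention would differ by
only ×1.069, far below replicate noise.

## True genotype matrix

G[i, j] = 1 iff mutation j lies on the root-to-leaf path of cell i's
clone. Rows are constant within a clone, and because mutations never
recur or revert, the mutation columns form a laminar family (any two
supporting cell sets are nested or disjoint) — the perfect-phylogeny
property, validated in the tests by an O(M²) pairwise check. Genotypes
are binary; zygosity is not modeled in SNV mode.

## Observed-matrix noise (SNV mode)

Noise is injected with **exact-count semantics**: for a requested rate r
and an eligible-entry pool of size n, exactly round(r·n) entries are
altered, chosen uniformly without replacement. Order of operations:

1. **Doublets.** round(doublet_rate · N) cells are chosen uniformly; each
   chosen row becomes the elementwise OR of its own true row and the true
   row of a uniformly chosen cell from a different clone (configurable).
   Doublet rows replace the original cells, keeping N fixed; flagged cells
   are excluded from every evaluation metric.
2. **Missing.** round(missing_rate · N · M) entries become 3, regardless
   of their value.
3. **FP/FN.** Among the remaining (non-missing) zeros, round(fp_rate · #0)
   flip to 1; among remaining ones, round(fn_rate · #1) flip to 0. The two
   flip sets come from disjoint value classes, so no entry is altered
   twice, and provenance masks record every alteration.

Defaults: FP 0.01, FN 0.2, missing 0.2, doublets 0 — the default row of
the benchmark grid (`SimConfig`, `TABLE_GRID`). A `bernoulli=True` option
switches to i.i.d. per-entry noise for users who prefer unconditioned
randomness over exact rates.

## Ultra-low-coverage read model

Coverage c ∈ (0, 0.5) is validated as "ultra-low"; depths above 2 are not
modeled because P(t ≥ 3) ≈ c³ is negligible in this regime. Per entry,
x ~ Uniform[0, 1) gives t = 2 if x < c², t = 1 if c² ≤ x < c, else 0
(strict inequalities; E[t] = c + c²). Variant reads:

- G = 0: v ~ Binomial(t, seq_error), default error 0.01.
- G = 1 (all variant sites are treated as heterozygous): one allele-dropout
  decision per entry with probability ado_rate (default 0.2); if ADO
  occurs, a fair coin silences either the reference allele (v = t) or the
  variant allele (v = 0); otherwise v ~ Binomial(t, 0.5).

D = 1 where v ≥ 1 and 3 (missing) otherwise — a covered site with zero
variant reads cannot be distinguished from an uncovered one, so this mode
never emits 0. No FP/FN/missing post-processing is applied; sequencing
error is the only false-positive source. The closed-form detection
probability per entry, used as a test oracle, is
f·[0.5c + 0.2c²] + (1−f)·[0.01c + 0.0099c²] at the defaults, where f is
the realized fraction of 1s in G. Note that f is a random quantity
determined by the tree shape (weighted mean root-path share of total
branch length); under reverse splitting with β = 0.2 its mean is ≈ 0.10,
giving mean missing percentages of ≈ 99.7% at c = 0.05 and ≈ 99.94% at
c = 0.01 for the 4000 × 5000, 8-clone configuration.

## Evaluation

- **V-measure** (β = 1): harmonic mean of homogeneity
  h = 1 − H(C|K̂)/H(C) and completeness cp = 1 − H(K̂|C)/H(K̂). Computed
  via scikit-learn; the test suite checks it against an independent
  entropy computation exhaustively on all partitions of up to 6 elements.
  The logarithm base cancels in the ratios.
- **Genotyping sensitivity / specificity / accuracy**: percentage of true
  1s / 0s / all entries reported correctly in an inferred binary matrix.
  Sensitivity (specificity) is undefined and raises when the truth has no
  1s (0s).
- **Consensus by majority vote**: per predicted cluster and site, missing
  entries are imputed independently per cell with fair coins, then the
  majority over the cluster's cells decides the consensus; an exact tie is
  broken by a seeded fair coin (reproducible runs). Every cell inherits
  its cluster's consensus row.
- Doublet-flagged cells are removed before any metric is computed.

## Experiment orchestration

A grid varies exactly one variable over its benchmark values while all
others stay at defaults, with 5 replicates per cell by default. Child
seeds derive deterministically from (base seed, variable, value,
replicate) via CRC-32, recorded in each dataset's manifest so any
artifact is reproducible from the manifest alone. The diagnostic heatmap
colors each (mutation, cell) pixel by its observation category — true
negative grey, true positive light blue, false positive dark red, false
negative dark blue, missing white — with cells clone-blocked under a clone
color bar.

## Problem sizes and numerical choices

- The dispersion statistic in `scripts/acceptance.py` averages 300
  replicate trees per β (the statistic stabilizes well below that); the
  low-coverage missing rate averages 5 seeded runs of the full
  4000 × 5000 configuration.
- All randomness flows through `numpy.random.Generator`; a single integer
  seed reproduces topology, intervals, branch lengths, placements and
  noise bit-identically. Derived seeds stay below 2³¹.
- Interval arithmetic uses half-open [s, e) intervals, so child intervals
  partition the parent without endpoint double-counting; all partition
  checks use a 1e-9 absolute tolerance.

## What the generator does and does not emulate

The simulator reproduces the error *structure* of scDNA-seq genotype
matrices — exact FP/FN/missing rates, doublets, extreme low-coverage
missingness, skewed clone sizes — but not read-level artifacts (no FASTQ/
BAM, no locus-specific amplification bias, no copy-number alterations, no
mutation loss or recurrence, no per-site coverage heterogeneity). Passing
benchmarks here therefore demonstrates an algorithm's robustness to the
modeled noise processes at their configured rates, not to every artifact
of real amplified single-cell libraries.

## Known limitations

- Reverse splitting with small β produces interval lengths spanning many
  orders of magnitude; the non-empty-clone guarantee then rests on the
  repair step, and several clones are singletons. Cluster-size dispersion
  saturates near its combinatorial ceiling (SD ≈ 150–160 for K = 8,
  N = 500) and varies only mildly with β, although the decrease in β
  remains strictly monotone.
- The low-coverage missing rate inherits the tree-shape randomness through
  f (above); its replicate SD at c = 0.05 is ≈ 0.2 percentage points.
- Doublet construction (OR with a uniformly drawn partner from another
  clone) is one plausible mechanism among several; the partner-pool choice
  is configurable.
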