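# Methods

This note documents the models and estimators implemented in
`paleodiv`, the conventions chosen where the literature leaves room,
and what the synthetic benchmarks do and do not demonstrate.

## Data model

The primary object is a taxon x stratigraphic-unit matrix of
non-negative integer *specimen* counts (one cell = number of physical
specimens, not collections), with ordered unit metadata: ordinal
position, base and top ages in Ma (base > top), and an optional
biostratigraphic zone label.  Taxa with zero total specimens are
dropped at load with a warning — every analysis conditions on a taxon
having been sampled at least once.  Genus-level tables are produced by
summing congeneric rows under an explicit species→genus lookup; a
first-whitespace-token splitter is provided for binomial labels but is
never applied implicitly, because taxon labels are treated as opaque
strings.

## Time binning

* **Zone binning** collapses contiguous runs of units sharing a zone
  label; non-contiguous zone membership is an error because a
  biostratigraphic bin must be a stratigraphic interval.
* **Per-unit binning** is the identity.
* **Stochastic age binning** lays equal-width bins (default 0.5 Ma)
  across the section's age span.  Edges fall on multiples of the width
  by default, expanding outward so the section is fully covered; an
  alternative anchors the first edge at the section's base age.  Each
  individual specimen is assigned independently and uniformly at
  random to one of the bins that *overlap* its unit's age bracket
  (positive overlap length; edge-touching does not count).  Uniform
  choice over eligible bins is the default because a specimen's
  within-unit position is unknown; weighting by overlap length is
  available as a configuration option (`assignment=overlap_weighted`)
  for users who prefer to model the bracket as uniform in time.  One
  hundred replicate datasets are the default; replicate r draws from a
  generator seeded by (seed, r), so any replicate can be regenerated in
  isolation.  Unit ages are user-supplied inputs; the packaged fixture
  carries illustrative placeholder ages only.

## Assemblage distances and zone redefinition

Pairwise faunal similarity between units uses the corrected Forbes
coefficient

    F = a(n + sqrt(n)) / [ a(n + sqrt(n)) + 1.5 b c ],  n = a + b + c,

with distance D = 1 − F; F is forced to 1 for identical and 0 for
disjoint presence sets.  Because presence sets harvested from
assemblages with different abundance evenness are not comparable under
incomplete sampling, distances are computed on evenness-standardised
draws: both units are subsampled without replacement to the same
specimen count m = min(N₁, N₂, cap), each draw is reduced to a
presence set, and D is averaged over replicates (default 1000).  With
m < 2 the value is emitted with an explicit unreliability warning.

Zone redefinition is constrained agglomerative clustering: only
stratigraphically adjacent clusters may merge, each step taking the
admissible merge with the smallest Ward-type dispersion increment
computed on squared dissimilarities via the Lance–Williams update.
Cumulative dispersion gives the dendrogram heights (increments are
floored at zero in the rare case of a non-embeddable input, keeping
heights monotone).  Cutting the tree at k necessarily yields k
contiguous zones; labels are inherited from the original zones by
majority membership with ties going to the older zone, but the labels
are cosmetic — the partition is the result.  The dendrogram exports to
Newick with branch lengths equal to height increments.

## Coverage-standardised richness

Coverage of a bin is estimated by Good's u = 1 − s₁/N.  A subsampling
trial shuffles the bin's specimen list and draws one specimen at a
time; the first time taxon i appears it contributes its coverage share
fᵢ = (nᵢ/N)·u, and drawing stops as soon as accumulated coverage
reaches the quorum.  The taxon that crosses the quorum is *included*
in the trial's richness (the exclusive rule is available as a flag;
with equal abundances and no singletons the inclusive rule gives
exactly ceil(q·S), which is the convention the tests pin down).  The
estimate is the mean over trials (default 1000).  A bin with u below
the quorum cannot be standardised to it and is flagged not-reached
rather than given a value.  Optional refinements found in some SQS
implementations (dominant-taxon exclusion and similar) are not applied.
Quorums default to {0.6, 0.7, 0.8, 0.9}; 0.6 is typically the highest
level reachable in every bin of a sparse section.  Under the
stochastic binning scheme SQS runs per replicate and the cross-
replicate mean is reported.

## Turnover rates

For a window anchored at bin i the counts are: two-timers t2 (sampled
in i and i+1), three-timers t3 (i, i+1, i+2), part-timers p (i and
i+2, not i+1), and gap-fillers g (i+1 and i+2, not i, but sampled in
some earlier bin — range-through evidence that the taxon existed in
i).  "Sampled before i" means any earlier bin by default; restricting
it to bin i−1 is a switch.  The extinction rate

    mu = log( (t2 + p) / (t3 + p + g) )

estimates −log of the survival probability of the i+1→i+2 transition,
so the value is attributed to bin i+1, the bin at whose end the
extinction it measures occurs; this attribution is what makes a
simulated pulse in bin k peak at bin k.  In the perfect-sampling limit
p = g = 0 and mu reduces to log(t2/t3).  Undefined rates (zero
numerator or denominator, or a window touching a missing bin) are NaN
and stay NaN through every aggregation — they are never imputed as
zero.

A precision refinement is available behind
`third_bin_test="range_through"`: the third-bin sampling test
"sampled in i+2" is relaxed to "sampled in i+2 or later", which can
only enlarge the survivor classes (t3, p, g).  It is identical to the
plain estimator under perfect sampling but is *not* the default: the
extra survivor evidence is not matched by a corresponding term in the
numerator, so under heavy subsampling it buys variance reduction at
the price of a downward-biased rate, and the unbiased plain estimator
is used everywhere results are reported.

Sampling heterogeneity is standardised by classical rarefaction:
each iteration draws a fixed quota of occurrences per bin without
replacement (default quota 5, 10,000 iterations — suited to sparse
half-million-year bins holding a handful of occurrences); bins below
quota are excluded, per-bin rates are averaged over the iterations in
which they are defined, and origination is computed by running the
same machinery on the time-reversed record (exact duality, tested).
Replicate rate series are summarised per bin by the median over
defined replicates and a bootstrap standard error of the median
(1000 resamples); the bootstrap is used because the sampling
distribution of a median of skewed, occasionally-undefined rates is
not well approximated by a normal-theory formula.

The estimator has a data demand worth stating: after rarefaction the
two/three-timer classes must remain populated, and the earliest
windows — which have little prior record to supply gap-fillers — are
systematically biased upward when per-bin detection is weak.  The
synthetic benchmarks therefore rarefy to a quota of 150 occurrences
per bin (against per-bin totals in the thousands), where the estimator
is well calibrated; with the quota at 5 on such rich simulated bins
almost all sampling information is discarded and no rate estimator is
informative.

## Synthetic generator

Truth is generated by a discrete-bin birth–death process: each taxon
extant in bin i dies at the bin's end with probability μᵢ, and each
extant lineage independently spawns a new taxon entering bin i+1 with
probability λᵢ₊₁.  Discrete bins (rather than continuous time) make
"true per-bin extinction probability" unambiguous, which is what the
rate estimators are judged against.  Preservation draws a lognormal
relative abundance per taxon (default log-mean 0, log-sd 1 — a few
dominant taxa, many rare ones) and Poisson specimen counts with mean
abundance x per-bin sampling intensity.  Unsampled taxa stay in the
truth record, so Signor–Lipps-style backward smearing of a sharp pulse
is reproducible.  Canonical study conditions (the defaults): 20 bins
of 0.5 Ma, 200 initial taxa, background origination and extinction
0.05 per bin, pulse extinction 0.6.

The packaged "texas-like" fixture is built differently — by direct
assembly, so its structure is exact rather than a birth-death draw:
11 units carrying five contiguous community blocks, 65+ single-unit
endemic taxa, within-block shared taxa, four low-abundance
long-ranging lineages crossing block boundaries, a richness peak
(Arroyo-like, 36 taxa) followed by a trough (Choza-like, 6 taxa), and
specimen counts of 1 + Poisson(abundance x intensity).  Sub-seeds are
tried deterministically until the realised singleton-specimen fraction
lands in the 0.15–0.22 band typical of such tables; the accepted
sub-seed is recorded in the fixture's truth file.  Unit names and ages
are decorative placeholders for readability; the fixture is synthetic
and is labelled as such in its filenames.

## What the benchmarks show — and do not

The pulse-recovery experiment (50 runs; one 0.6-extinction bin against
0.05 background; lognormal sd-0.5 intensity multipliers at mean
sampling rate 8 per taxon-bin; quota 150, 300 iterations) demonstrates
that the rate machinery localises a severe pulse and keeps background
exp(−mu) within a few percent of true survival *under the generator's
assumptions*: independent Poisson preservation, no geographic or
taxonomic structure in sampling, known bin membership.  The SQS
experiment (flat true richness, 10x intensity spread) demonstrates
variance reduction relative to raw counts, not unbiasedness of any
single bin's estimate.  Real sections add correlated preservation,
facies-dependent sampling, and age-model error that these benchmarks
deliberately exclude; passing them shows the estimators are
implemented correctly, not that a real dataset's curves are free of
bias.

## Numerical conventions

* Ages decrease toward the present; all interval tests use an absolute
  tolerance of 1e-9 Ma to absorb floating-point edge effects.
* SQS quorum crossing uses a 1e-9 tolerance so exact rational coverage
  sums (e.g. six shares of 0.1 against quorum 0.6) count as crossed.
* Stochastic stages derive independent child generators from
  (seed, replicate/stage tokens) via NumPy `SeedSequence`; identical
  seeds give byte-identical outputs, and no stage shares a stream with
  another.
* Degenerate inputs fail loudly: empty bins have undefined coverage,
  two empty presence sets have no defined similarity, a zero-width age
  bin is an error, and rates with empty numerator or denominator are
  NaN, never zero.
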