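# Methods

## Problem and scope

`maizefp` models the desk side of designing a fixed SNP genotyping array
for maize variety identification: starting from a large candidate marker
set assayed on an evaluation panel of inbred lines and F1 hybrids, screen
down to a few thousand loci that call cleanly, are polymorphic across
heterotic groups, sit one-per-gene-region across all ten chromosomes, and
are manufacturable as array probes. Because real two-channel scanner data
for such panels is rarely public, the package pairs the analysis stack
with a synthetic-data generator that reproduces the *statistical*
structure such a study assumes, so every stage can be validated against
planted ground truth.

## Signal model

A two-channel measurement (x, y) — A-allele and B-allele signal — maps to

    theta = (2/pi) * arctan(y/x),   r = x + y

so theta is 0 for a pure A homozygote signal, 1 for pure B, and 0.5 for a
balanced heterozygote. The Manhattan total `r = x + y` is the package's
radius convention, consistent with the angle normalization; a Euclidean
radius is available behind `ClusterBuildConfig(radius="euclidean")`. A
point with both channels zero has no angle; bulk operations treat it as a
failed measurement.

### Cluster files

Calling uses a per-locus *cluster file*: three genotype regions on the
theta axis plus a signal floor. Construction from a labeled panel:

1. the floor is `max(0.20 * median r, 0.20)` — relative so bright and dim
   loci are treated alike, with an absolute backstop so an all-weak locus
   is flagged rather than rescaled into callability;
2. above-floor thetas are clustered by one-dimensional three-means seeded
   at the canonical 0 / 0.5 / 1.0 genotype positions. The seeded Lloyd
   iteration is written in-package (a generic k-means would relocate
   empty clusters, destroying the genotype identity of each slot);
3. a cluster with at least 3 points shifts its center to the observed
   mean and takes halfwidth `max(3*SD, 0.05)`; a smaller occupied cluster
   keeps the canonical center but widens its region to cover its points
   (the curation goal is minimum missing rate subject to disjoint
   regions); an empty slot keeps a default region (canonical center,
   halfwidth 0.05, `occupied=False`) so a rare heterozygote appearing in
   later data remains callable;
4. regions are made disjoint by truncating at midpoints between adjacent
   centers at call time.

Calling assigns the region containing the point's theta whose floor its
signal exceeds; among candidates on a shared boundary the nearer center
wins and an exact midpoint goes to the lower-theta region. Confidence is
`1 - min(|theta - center|/halfwidth, 1)`.

## Locus quality score

The composite per-locus quality score is the geometric mean of four
subscores in [0, 1], mirroring the four cluster characteristics that
commercial genotyping software summarizes (angle, dispersion, overlap,
intensity). It is a documented analog, not a numeric reproduction of any
proprietary score; values are comparable within this package only.

* angle — min gap between adjacent occupied centers, normalized by 0.5;
* dispersion — `1 - mean within-cluster theta SD / 0.1` (the 0.1 cap is
  where a cluster is as wide as a fifth of the axis and the subscore
  bottoms out);
* overlap — 1 minus the fraction of points inside another occupied
  region's untruncated band;
* intensity — fraction of points above the floor.

Defect flags use strict "more than" thresholds: more than ⌈5 % of n⌉
failed samples (the count form "more than 5 of 96" is authoritative —
note 5/96 marginally exceeds a naive 5 % rate, so the allowance rounds
up), more than 3 Mendelian-inconsistent trios, more than 5 heterozygous
inbred lines, any occupied center more than 0.15 from its canonical
position, and median signal below the floor.

## Staged selection

Stage 1 keeps quality ≥ 0.70 (inclusive). Stage 2 keeps loci within the
missing-data allowance, with no defect flags, and with perfect duplicate
reproducibility where duplicate pairs are informative (loci with no
informative pair are not penalized). Stage 3 drops copy number ≥ 2 and
MAF < 0.20 (0.20 itself kept), computing MAF on the inbred subset with
allele counting AA→2A, AB→1A+1B, BB→2B, then keeps one marker per genic
region by category priority exon > promoter > 3'UTR > 5'UTR > intron
(priority dominates quality; ties break by quality then position).
Stage 4 drops designability < 0.40 and, if survivors exceed the target
size, removes markers one at a time from the densest 1000-kbp window,
worst first (designability ≥ 0.60 preferred, then quality, then
designability) — a deterministic evenness-preserving trim, which is this
package's policy where the original procedure is unspecified. Survivor
sets are nested and every dropped locus carries exactly one
first-failure label.

Genuinely open choices made here: perfect (1.0) duplicate concordance
required at stage 2; the genic-category priority order inferred from the
exon-dominant composition of curated panels; boundary semantics follow
the screen's wording exactly (quality inclusive, MAF/designability
strict).

## Synthetic data

The generator emulates a 96-sample evaluation study: 10 chromosomes at
maize-like lengths, six heterotic groups (8 inbreds each), 40 hybrids of
which 22 form parent/parent/F1 triplets, two near-identical line series
(a mutant series at 0 divergence and a backcross series at 2 %,
emulating the >97 %-similarity groups such studies carry), and 2 exact
duplicates. Group allele frequencies follow a Balding–Nichols model
(uniform ancestral frequency, per-group Beta draws at divergence F=0.05;
the true differentiation of maize heterotic groups is not calibrated —
the parameter is exposed). Inbreds are fully homozygous (an optional
purity knob introduces off-type homozygotes, default off); F1s are exact
Mendelian combinations.

Intensities place genotypes at theta 0.05 / 0.50 / 0.95 with angle SD
0.02 and total signal 1.0 ± 0.1. Defect classes perturb emission the way
failing array markers do: weak signal (total signal at 5 % of nominal
for 90 % of samples), excess missing (8 % of samples dropped below the
floor), shifted clusters (+0.20 theta), multi-copy compression (theta
span compressed 0.4× toward 0.5), heterozygous inbreds (8 inbred lines
emitted at the AB angle), pedigree failure (5 F1s emitted at a
non-Mendelian angle). Default defect fractions total ~14 % of loci.
Designability scores draw from a three-band mixture (1.5 % in
[0.40,0.60], 27.5 % in (0.60,0.80], 71 % in (0.80,1.00]); genic
categories draw at 43/21/22/9/5 % for
exon/promoter/utr3/utr5/intron. All randomness flows from one seed
through named substreams, so layers regenerate independently and runs
are bit-reproducible.

The planted-selection scenario (used for exact pipeline-recovery checks)
assigns each non-good locus exactly one violation and gives planted-good
loci safety margins (group frequency in [0.40, 0.60], designability
≥ 0.60, singleton genic regions). For that scenario the population is
drawn in an exact-group-frequency mode (stratified assignment of
`round(p·n)` B-carriers per group), because independent Bernoulli draws
on 56 inbreds can legitimately push an empirical MAF across the 0.20
gate — the planted guarantee is about construction, not sampling luck.

What the generator does *not* emulate: linkage disequilibrium between
loci, per-channel affine scanner effects and batch drift, probe
cross-hybridization producing asymmetric cluster shapes, and
sequence-derived designability. Passing tests therefore demonstrate the
pipeline's correctness against its own model of array data, not
performance on any real scanner output.

## Problem sizes and numerical choices

Tests run the full pipeline on a 400-locus, 96-sample panel (shared
fixture) plus a 5,000-locus planted-recovery run; the acceptance script
uses a 500-locus zero-noise triplet scenario and a 5,000-locus
default-noise selection run — sizes chosen so a complete desk run stays
in the minutes range while keeping ≥ 30 loci per defect class. Boundary
comparisons are exact (no epsilon) except region coverage of sub-shift
clusters, which pads by 1e-9 to absorb polar round-trip error. Lloyd
iteration caps at 50 rounds (convergence is typically < 10 on 1-D data);
ties in calling resolve to the lower-theta region; the histogram's final
bin is right-closed so a differential rate of exactly 1 is counted.

## Known limitations

* The quality composite is scale-consistent but not calibrated to any
  vendor score; the 0.70 stage-1 gate transfers the *wording* of the
  screen, not a cross-calibrated operating point.
* The evenness-preserving trim is one reasonable policy; the original
  candidate-to-panel reduction is not documented at that granularity.
* Copy number is consumed as locus metadata (synthetic truth); the
  multi-copy intensity signature (compressed theta span) is generated
  and detectable but detection is advisory, not the stage-3 gate.
* Pairwise statistics are O(n² · loci) dense comparisons — fine for
  hundreds of samples, not engineered for biobank scale.
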