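# Methods

`hybmap` builds sex-specific recombination maps for a nematode double cross
from low-coverage sequencing of F2 progeny, and ships a meiosis simulator
that generates every input the pipeline consumes, so the whole analysis is
exercised end to end without external data.

## The cross and what makes it phasable

Three inbred strains — CA (the reference), WA and LR — are crossed to
produce two F1 hybrids: a CA/WA male and a CA/LR hermaphrodite. Their F2
progeny carry exactly one recombinant haplotype from each F1. Because WA
haplotypes can only be transmitted through the male's sperm and LR
haplotypes only through the hermaphrodite's ova, the four possible F2
genotypes (CA/CA, CA/WA, CA/LR, WA/LR) decompose *uniquely* into a
(paternal, maternal) strain pair, and every genotype transition along a
chromosome is a crossover in an identifiable parent. Sex determination is
XX/XO: the male's single X has no pairing partner, is transmitted intact,
and yields no male X map.

## Meiosis model (simulator)

Each meiosis is modeled with four chromatids (two sisters per homolog).
Crossover count per bivalent is either obligate (exactly 1, plus a second
with probability `double_co_rate`) or Poisson(`co_per_meiosis`). Each
crossover exchanges the distal segments of one chromatid from each homolog,
both chosen uniformly among the two sisters; the transmitted chromatid is
drawn uniformly from the four. With a single obligate crossover this gives
the classical result that half of transmitted chromatids are
nonrecombinant, and a per-chromosome map length of 50 cM.

A caveat discovered by exact enumeration of this exchange process: the
often-quoted rule "expected map length = 50·c cM for c crossovers" holds
only for c ≤ 1. At a fixed two crossovers the expected number of
*observable* strain transitions per transmitted chromatid is 0.75, not 1.0
(a three-strand double places material of the same strain on both sides of
the second exchange point), so the expected map is 75 cM. The unit tests
assert the enumeration-derived values.

Crossover positions follow a piecewise-uniform density with relative weight
`arm_weight` (default 3) on the chromosome arms (default: the outer
quarters), 1 in the center, and 0 inside configured suppressed regions —
the minimal landscape reproducing the arm-biased recombination of
holocentric nematode chromosomes, and enough to emulate the one-sided
crossover suppression seen in some hybrid chromosome pairs.

Optional single-locus viability selection removes F2 whose haplotype of a
given parent carries a disfavored strain at a locus, with survival
probability equal to the relative viability v. Among nonrecombinant
chromatids of that parent the surviving haplotype ratio is then 1/v, which
the distortion analysis recovers.

## Simulated data and its defaults (the study conditions)

* **Cohort**: 93 F2, all XX hermaphrodites; by default every F2 must carry
  a WA haplotype somewhere, emulating marker-validated cross-progeny.
  This conditioning is negligible at the full karyotype (~0.1% of
  candidates rejected) but substantially distorts single-chromosome
  experiments (it removes 1/4 of paternal gametes), so reduced-karyotype
  property tests set `require_wa=False`.
* **Karyotype**: six chromosomes (2n = 12), synthetic lengths 36.8, 28.4,
  24.4, 26.0, 23.9 and 17.2 Mb (X), summing to 156.7 Mb so the genome
  tiles into exactly 1567 100-kb blocks.
* **Marker panel**: biallelic sites, each homozygous in all three parents
  and private to exactly one strain, at 8900 sites/Mb (~890 per block) —
  the density of the real cross panel (~1.4 M sites / ~157 Mb). Density
  matters: see "no-call structure" below. Parental depths are Poisson
  (CA, LR: 86×; WA: 61×).
* **F2 sequencing**: per site, each haplotype contributes
  Poisson(coverage/2) reads (default coverage 5×); each read is reported
  as the opposite allele with probability `error_rate` (default 0.005, a
  generic short-read substitution-plus-misassignment rate; not a measured
  quantity). Read totals are conserved between draw and report.
* **Male X strain**: the direction of the grandparental cross fixing the
  male X is configurable (`male_x_strain`, default CA).

All randomness flows from one seed through per-stage `SeedSequence`
children; identical configurations give byte-identical outputs.

## Site selection

Sites are kept iff (1) all three parents are homozygous, (2) each parent's
depth lies within its genome-wide mean ± 3 SD window, (3) exactly two
alleles segregate, with (4) the minority allele private to one strain.
Rejections are typed (`missing`, `het`, `depth`, `not_biallelic`,
`not_diagnostic`) and every input site lands in exactly one class. Depth
bounds are computed genome-wide per strain, matching the single printed
window per strain that motivated the filter.

## Block genotyping

Within each non-overlapping 100-kb block, the reads carrying each strain's
diagnostic alleles are summed into (d_CA, d_WA, d_LR) and normalized to
fractions f summing to 1; shared-allele reads are uninformative and count
nowhere. Calls:

* CA/CA iff f_CA > 0.95;
* CA/WA iff f_LR < 0.05 and |f_CA − f_WA| ≤ 0.10;
* CA/LR iff f_WA < 0.05 and |f_CA − f_LR| ≤ 0.10;
* WA/LR iff f_CA < 0.05 and |f_WA − f_LR| ≤ 0.10;
* otherwise no call (`ambiguous`), with additional no-call classes for
  zero or sub-threshold total depth (default gate: 20 classified reads,
  configurable to 0) and for X genotypes incompatible with the intact
  male X.

The heterozygote condition is deliberately the *balance* direction
(|f_i − f_j| small): under diagnostic-allele counting a true heterozygous
block has both informative fractions near 0.5, so the opposite inequality,
which has circulated in print, would reject every true heterozygote while
homozygotes are already captured by the 0.95 rule. The printed direction
remains available (`het_rule="printed"`) for comparison. The four rules
are mutually exclusive over the whole fraction simplex (verified by dense
grid search and asserted at run time).

**No-call structure.** The balance gate absorbs two noise sources: Poisson
depth fluctuation and the fixed multinomial imbalance of per-strain site
counts within each block. At 5× and ~890 sites/block a true heterozygous
block is no-called a few percent of the time; blocks whose site-count
imbalance exceeds ~0.1 no-call one heterozygote class for essentially
*every* F2. Such blocks then show a ~1:0:1:1 called composition, are
flagged by the distortion test, and are removed by the block filter — in
the neutral full-scale run ~1% of blocks drop this way, an order of
magnitude above the 0.1% chance rate, and deliberately so: the filter is
removing systematically miscallable blocks, not noise. At sparse marker
densities this effect dominates (at 2000 sites/Mb ~30% of heterozygous
blocks would be no-called), which is why the simulator's default density
is the study's real density rather than a smaller convenience value.
Classifier accuracy *among emitted calls* exceeds 99% per true class at
study conditions; no-calls are tracked separately and anticipated by the
uncalled-fraction block filter.

Block filters: ≥ 100 diagnostic sites, ≤ 30% of F2 uncalled, and
segregation-distortion p > 0.001 (Pearson χ² against 1:1:1:1 on the four
autosomal classes, df 3, or 1:1 on the two admissible X classes, df 1; no
continuity correction — expected counts are ≥ 20 at n = 93).

## Phasing and crossover calling

Calls decompose into paternal ({CA, WA}) and maternal ({CA, LR}) label
vectors over kept blocks; no-calls become missing in both. A crossover is
called at every strain change between consecutive *called* blocks; its
interval runs from the end of the left called block to the start of the
right one (missing blocks widen it), with the midpoint as point estimate.
Terminal missing blocks generate no crossover, so a crossover falling
inside the first or last block of a chromosome is below marker resolution
by construction — the oracle-equivalence test excludes those chromatids
(~1–2% on a 10–20 Mb chromosome) and requires exact count recovery on all
others. No smoothing is applied: every transition counts, and chromatids
with > 3 crossovers are flagged suspect rather than edited. Cohort tallies
exclude the paternal X and chromatids with fewer than two called blocks.

## Map construction

Kept blocks are loci at their physical midpoints, in assembled reference
order (no de novo marker ordering). The interval recombination fraction is
crossover-based: each phased crossover is assigned once to the inter-bin
interval containing its midpoint, and r of an interval is that count over
the chromatids informative there (a called bin on each side). On complete
data this reduces to the plain adjacent-bin discordance ratio; unlike that
ratio it does not lose the crossovers whose own mixed-haplotype bin is
uncalled — which is the *typical* case, since a bin containing a crossover
has ambiguous depth fractions. (The strictly pairwise estimator recovers
only ~20% of the map, ~10 cM instead of ~50.) Summed interval counts equal
the total phased transition count exactly, giving the internal consistency
check the tests assert. r is capped at 0.5 with a warning; undefined
intervals contribute 0 cM and are flagged, not interpolated.

Cumulative positions are Σ m(r)·100 cM with m the mapping function —
Morgan (identity) by default, appropriate for dense bins where per-interval
r ≪ 0.1; Haldane and Kosambi are selectable and differ only at the percent
level here. Arm/center summaries interpolate cumulative cM at the arm
boundaries and report per-region cM/Mb and the arms:center ratio. There is
no paternal X map.

## Distortion analysis

The distortion *filter* runs before map building, but distortion
*reporting* uses the unfiltered call matrix, since biologically coherent
distortion extends over whole chromosomes. Reported quantities:

* per-block χ² tests (above);
* the nonrecombinant inheritance ratio — among chromatids with zero
  crossovers, the favored:disfavored haplotype count ratio (≥ 1 by
  orientation; infinite ratios flagged). Under single-locus viability v
  against one haplotype the expected ratio is 1/v, recovered by the tests
  at v ∈ {1, 0.5, 0.125};
* distortion gradients along the chromosome. Two trend tests are
  provided. `distortion_gradient` permutes bins and is calibrated for
  exchangeable series (i.i.d. measurement noise). For cohort frequency
  series it is badly anticonservative — adjacent bins share chromatids, so
  a neutral cohort's series is a smooth autocorrelated process with few
  effective degrees of freedom, and bin permutation rejects neutral
  cohorts at ~100× the nominal rate. The pipeline therefore uses
  `chromatid_gradient_test`, an exact randomization test built on the
  group invariance of the neutral null: neutrality makes the cohort
  distribution invariant under independent CA↔LR (or CA↔WA) relabeling of
  whole chromatids, which reduces to sign flips of per-chromatid
  position-weighted scores. It is calibrated on neutral cohorts (verified
  at nominal rate in the tests, and empirically robust to the informative
  missingness pattern above), and detects end-of-chromosome viability
  selection with the slope sign pointing toward the selected locus.
  Gradient reports run on kept blocks to avoid the systematically
  miscallable blocks.

## Problem sizes used by the shipped analyses

The numbered drivers and the verification suite run the full study-scale
configuration (93 F2 × 1.4 M sites × 6 chromosomes, ~40 s) once and share
it; focused property experiments use single chromosomes of 10–25 Mb with
93–1500 F2, with marker density raised to 30,000/Mb only in the
high-information oracle regime (30×, error-free) where block-level
ambiguity must be negligible. The acceptance script reruns the full
study-scale pipeline from scratch at the given seed.

## What the simulator does not emulate

Uniform site placement (no repeat deserts or coverage troughs, so the
≥ 100-sites filter never fires on synthetic data), no mapping bias,
reference bias, indels, or base-quality structure; no crossover
interference model beyond the count (a second crossover is placed
independently); no gene conversion; selection acts at a single locus with
a single parent-of-origin. Passing tests therefore demonstrate that the
*method* — filters, classifier, phasing, mapping, distortion statistics —
behaves as designed under its own generative assumptions, not that it is
robust to alignment artifacts or complex incompatibility genetics.

## Known limitations

* Map resolution is one block (100 kb); crossovers in terminal blocks are
  invisible, biasing map length down by ~0.5–1% and the nonrecombinant
  fraction up by a similar margin.
* The fraction classifier has no per-site error model; at coverages well
  below 5× the depth gate (not the thresholds) dominates callability.
* Inter-strain segments are modeled as freely recombining; structural
  rearrangements are representable only phenomenologically as suppressed
  regions.
* The χ² distortion p-values ignore the multiplicity of 1567 blocks;
  the filter is a screening rule, not an inference.
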