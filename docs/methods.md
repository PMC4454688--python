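# Methods

This note documents the models, numerical choices and limitations behind
`embryomito`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## qPCR relative quantification

The 2^−ΔΔCt method assumes an amplification efficiency of exactly 2 per
cycle for both the mitochondrial and the Alu assay; no efficiency
correction is applied. Triplicates are aggregated by the arithmetic mean.
A replicate-scatter QC flag is raised when the sample standard deviation
exceeds `max_sd` (default 0.5 cycles); flagged samples are still
quantified — a total pipeline with an explicit flag is preferable to
silently dropping few-cell samples. A missing replicate is an error, not
an imputation target. One reference ΔCt is supplied per analysis run,
mirroring a single constant reference sample; no inter-run calibration is
attempted. Classification against the viability cutoff uses a strict
inequality (RQ > cutoff ⇒ high/abnormal): in the bundled reference
dataset a sample at RQ 0.0033 is high while no sample sits exactly at
0.003, so the strict rule reproduces all labels deterministically.

## Read-depth copy-number calling

* **Grid.** Real grids hold a fixed number (100) of uniquely mapping
  36-mers per bin, hence variable genomic width. Any such grid can be
  supplied as a TSV; the bundled synthetic builder uses fixed-width bins
  (default 120 bins per chromosome, chr1–chr22) with the mappability
  content recorded. 120 bins/chromosome is a deliberate down-scaling —
  genome-wide mappability grids run to tens of thousands of bins — chosen
  to keep simulations light while remaining dense enough that
  chromosome-median estimates are stable.
* **GC normalisation.** 1%-GC strata (adjacent strata merged until each
  holds ≥ 20 bins) are scaled by the ratio of the stratum median to the
  global autosomal median. Stratum medians are computed from autosomal
  bins only, so a sample's sex-chromosome dosage cannot distort the bias
  curve. The in-silico reference enters as a per-bin `reference_weight`
  (expected relative depth, median 1; identity by default), divided out
  after the GC step. The output is rescaled so the autosomal median
  equals the input's, making normalisation a pure reshaping.
* **Copy number.** CN_i = normalised count_i / median(autosomal
  normalised counts) × 2, anchoring the autosomal median at the diploid
  state. All-zero samples and zero autosomal medians are hard errors
  (failed samples, not data).
* **Smoothing.** 13-bin sliding median per chromosome. At chromosome
  edges the window shrinks symmetrically (half-window
  `min(6, i, n−1−i)`), which keeps the estimate centred and discards no
  bins; windows never cross chromosome boundaries.
* **Calls.** Chromosome state from the median of smoothed values: gain
  ≥ 2.5 copies, loss ≤ 1.5 — midpoints between integer copy states, the
  natural deterministic choice, exposed as options. Sex chromosomes are
  excluded from the normalising median; they are called against expected
  copies for a declared sample sex (shifted to a diploid-equivalent
  scale) or reported uncalled otherwise. Coordinates are 0-based
  half-open throughout and a read belongs to the bin containing its
  start. `min_mapping_score` has no universal value across aligners and
  is configuration (default 20).

## Mitochondrial sequencing measure

The mito fraction is 100 × mito bases / (mito + nuclear aligned bases).
Percent-of-total is the convention fixed here; since the mitochondrial
genome contributes well under 1% of aligned bases, percent-of-total and
percent-of-nuclear differ by far less than measurement noise. The
fraction is scale-invariant in sequencing depth. Heteroplasmy calls
require depth ≥ 20 and alternate fraction ≥ 0.05 (defaults chosen as
conventional shallow-calling gates; at ~150× depth a 5% minor allele is
comfortably above the binomial noise floor of a 0.2% error rate);
fractions above 0.95 are homoplasmic-alternate. The genome is handled as
linear positions 1..16,569 — pileup input is already position-resolved,
so no junction logic is needed. Mutation-load comparison counts
heteroplasmic sites per sample and applies a Welch t-test; groups of
size < 2 skip the comparison with a warning.

## Viability threshold

Two modes. *Fixed*: cutoff 0.003 (qPCR RQ) or 0.07 (NGS percent).
*Derived*: the smallest positive multiple of `rounding_grid` (default
0.0005) strictly greater than the maximum value among training
implanters — by construction no training implanter is flagged, so
training NPV is 100% whenever any embryo lies above the cutoff. Whether
the canonical 0.003 arose by rounding or as the exact training maximum
is not knowable from summary data; both modes are supported without
asserting either. NPV is defined for the non-viability prediction: the
share of above-cutoff embryos that failed to implant. The blinded
harness requires disjoint embryo ids between training and test and
touches test outcomes only inside evaluation. Outcomes are binary
(ongoing clinical pregnancy vs not); biochemical-only pregnancies are
not modelled.

## Cohort statistics

Unpaired two-tailed t-tests compare RQ between groups; Welch's variant
is the default (group variances on the RQ scale are rarely comparable),
with the pooled variant and an optional log2 transform available. The
younger/older maternal-age boundary is 38 years (younger ≤ 37), exposed
as configuration. No multiple-testing correction is applied across the
three comparisons; p-values are reported raw. Per-age summary rows
report range and mean per ploidy group, with the mean marked
not-applicable for single-embryo groups.

## Synthetic-data generator

The generator emulates the cohort structure the analysis assumes:

* **Cohort.** Default n = 302 blastocysts; per-age sampling weights and
  aneuploidy rates follow the bundled 302-embryo cohort composition
  (ages 26–42, 203 euploid / 99 aneuploid overall). Aneuploid embryos
  carry one whole-chromosome event (trisomy or monosomy, equally
  likely); mosaicism and segmental events are out of scope.
* **Latent RQ.** Log-normal with σ(ln) = 1.0 — observed per-age ranges
  span about two orders of magnitude, and multiplicative variation is
  the simplest consistent model. The geometric mean for a euploid
  blastocyst at the reference age of 38 is 0.0015; per-year
  multiplicative age effects are 1.10 (blastocyst, rising) and 0.85
  (cleavage, falling; cleavage baseline 0.05), and aneuploidy multiplies
  RQ by 1.8. Effect magnitudes are configuration, not constants: the
  available evidence fixes directions and significance, not sizes, so
  defaults were calibrated such that n = 302 cohorts reach p < 0.05 for
  the age and ploidy comparisons in ≥ 80% of replicates while nulled
  effects give uniform p-values (both properties are asserted by the
  test suite and recomputed by the acceptance script).
* **Outcomes.** Euploid blastocysts receive a known transfer outcome
  with probability 0.44, implanting with probability 0.47 once
  transferred (≈ 42 implanters per 89 transfers). Implanted embryos are
  drawn from the latent distribution truncated below the viability
  cutoff (0.003); non-implanters are drawn above it with probability
  0.30 and below otherwise. Whether elevated non-implanters follow a
  distinct distribution or the common tail is not identifiable from
  summary data; the generator uses the truncated common distribution,
  and the elevated share is configuration.
* **NGS fraction.** Tied to the latent RQ by a monotone affine map with
  a 0.03% background floor, calibrated so RQ 0.003 ↔ 0.07% — the paired
  cutoffs of the two assays — preserving cross-assay concordance.
* **qPCR.** Alu triplicates centre on a fixed baseline (20 cycles) plus
  a sample-level shift that cancels exactly in ΔCt; the mitochondrial
  centre is Ct(Alu) + reference ΔCt − log2(RQ). Each replicate gets
  independent Gaussian noise (default 0.25 cycles). The simulator emits
  ideal, uncapped cycle thresholds — the instrument cap (~40 cycles)
  is enforced on real-data ingestion, not on the generative model, so
  noise-free quantification recovers any planted RQ to machine
  precision.
* **Bin counts.** Expectation = mean reads/bin × (copies/2) ×
  gc_bias(GC) × reference weight, with a quadratic bias curve (default
  0.2 + 4·g − 5·g², mild and mid-GC-peaked) and negative-binomial
  sampling (variance μ + d·μ², d = 0.1 by default, reflecting WGA
  overdispersion of unquantified magnitude; d = 0 gives the Poisson
  limit). Default depth is 50 reads/bin; recovery checks run at 30.
* **Pileups.** Per-site depth Poisson (default mean 150×), alternate
  counts binomial at planted fractions, sequencing error 0.2%
  elsewhere.
* **Seeding.** One global seed; every operation draws from a substream
  keyed by (seed, operation tag, sample id), so cohorts are
  bit-reproducible and per-sample outputs do not depend on call order.

What the generator does **not** emulate: amplification dropout and
locus-specific WGA artefacts, segmental or mosaic aneuploidy,
between-run qPCR batch effects, aligner-specific mapping biases, and
strand- or context-dependent sequencing error. Passing tests therefore
demonstrate correctness of the computational machinery under the stated
statistical model, not robustness to every artefact of real embryo
biopsy data.

## Problem sizes

Simulation-based checks use 200 replicate cohorts (or samples) for
recovery/power estimates and 500 for null-calibration KS tests; the
synthetic grid holds 2,640 bins (22 × 120). These sizes keep the full
suite fast while leaving Monte-Carlo error well below the margins being
asserted.

## Known limitations

The caller targets whole-chromosome events only; segmental changes are
smoothed away by design. The derived threshold rule depends on the
training implanter maximum, a noisy extreme-value statistic — on small
cohorts the derived cutoff can sit a grid step away from the latent one
(measurement noise also shifts measured maxima above latent ones). NPV
estimates from cohorts with few above-cutoff embryos carry wide
binomial uncertainty, which the point metrics do not express.
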