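# Methods

## Decision statistic

Parentage is decided from Mendelian incompatibilities between rule-based
genotype calls at single-nucleotide variant loci.

**Genotype calling.** A locus is callable when 5–20 reads carry single-base
evidence (A/C/G/T; reads with indel descriptors, reference skips or N are
counted in depth but give no base evidence, and the window is applied to the
base-evidence count so that a homozygous-alternate call can always reach a
mutant fraction of exactly 1). Within the window:

- zero mismatching reads → homozygous reference;
- mutant base = highest-count non-reference base, requiring ≥ `min_alt_reads`
  (default 3, configurable — "more than 2 supporting reads") and no second
  non-reference base at or above that bar (diploid biallelic model; top-count
  ties are uncalled);
- mutant fraction 1.0 → homozygous alternate; in [0.25, 0.75] → heterozygous;
  in the gaps (0, 0.25) or (0.75, 1) → no call.

Band edges are evaluated in integer arithmetic (`4·alt ≥ depth`,
`4·alt ≤ 3·depth`), so no boundary case depends on floating-point rounding.
The depth ceiling exists because loci collecting many more reads than the
average fold-coverage are enriched for collapsed repeats and mapping
artefacts. Analysis is restricted to autosomes 1–22 by default: hemizygous
male X/Y violates the diploid genotype bands.

**Trio mode.** Informative loci: both presumed parents homozygous with
different alleles, and the proband callable (loci without a proband call are
excluded from the denominator by default — a denominator padded with
uncallable loci would dilute the rate with missing data; a toggle retains
them). The inconsistent rate against a tested parent is the fraction of
informative loci where the proband is homozygous with an allele different
from that parent's. Proband-heterozygous loci carrying an allele seen in
neither parent are reported as a diagnostic count, not in the numerator.

**Duo mode.** Denominator: loci where proband and the presumed parent are
both homozygous; numerator: opposing homozygotes.

Fewer than `min_informative` loci (default 100) yields an *inconclusive*
result rather than a rate: percentage estimates from tiny denominators are
noise. Loci present in a supplied recurrent-SNV blacklist are removed before
either count.

## Calibration and classification

The statistic has a nonzero biological baseline driven by low-coverage
genotyping error, so cutoffs are empirical: `cutoff = mean + Z·SD` over
rates from confirmed-biological analyses, with Z = 3 (trio) and Z = 5 (duo;
its wider biological/non-biological gap affords the stricter multiplier).
SD is the sample (n−1) estimator, with a population-SD option. A rate
exactly at the cutoff classifies as *not confirmed* — the conservative
boundary rule for a QC test. Shipped default cutoffs are 24.5% (trio) and
25.6% (duo); note that 24.5 differs in the last digit from
18.1 + 3·2.1 = 24.4 computed from the rounded baseline mean/SD, consistent
with derivation from unrounded baselines, and we keep 24.5 as the default
constant. Defaults encode a specific platform's baseline; any materially
different error profile (other chemistry, the bundled simulator) requires
local recalibration, which `run_end_to_end` demonstrates.

The cohort summary reports the misattributed-parentage (MP) rate as
`100·n_not_confirmed/n_families`, rounded to 2 decimals.

## Blacklist

Each analysis contributes its flagged (inconsistent) loci once; per-locus
counts are the number of *analyses* (paternity and maternity tests counted
separately) flagging it. Export keeps loci seen at least `min_recurrence`
times (default 2). Trio- and duo-derived blacklists are naturally kept
separate by accumulating them separately; `merged_with` provides the merged
variant.

## Synthetic-data generator

The simulator emulates the statistical structure the method relies on, not
a sequencer:

- **Locus panel** (shared by every sample in a cohort): 200,000 polymorphic
  autosomal loci — the monomorphic genome never enters the statistics and is
  not simulated — with alternate-allele frequency ~ Uniform(0.05, 0.5), the
  reference base being the major allele.
- **Genotypes**: Hardy–Weinberg parents, Mendelian child (one allele from
  each parent, chosen uniformly). Non-biological structures replace the
  father, mother or child with an independent Hardy–Weinberg individual
  after transmission, mirroring how known non-parentage families are formed
  by re-assigning parents across families.
- **Coverage**: per-locus depth ~ Poisson(`mean_depth` × b), where the bias
  b is lognormal (mean 1, σ = 1.5) and **shared across samples**. This
  models mappability/GC coverage inhomogeneity, which is locus-intrinsic and
  therefore correlated between samples; it is what leaves hundreds of loci
  simultaneously callable in three samples at 1-fold. Under independent
  Poisson(1) depths the probability that one locus shows 5–20 reads in all
  three members is ≈5×10⁻⁸ and a panel of this size would yield no
  informative loci at all. With the shared bias, a 1-fold trio yields
  ~200–250 informative loci and a duo ~2,000–2,300 both-homozygous loci,
  the same order as real 1-fold data. Setting `coverage_bias_sigma = 0`
  recovers the pure independent-Poisson model (used by the distributional
  unit tests, which are conditional-on-bias statements).
- **Systematic-error sites** (0.5% of the panel): tenfold extra coverage
  bias, and each sample observes an arbitrary apparent alternate-read
  fraction ~ Beta(0.3, 0.3) detached from the true genotype — alignment
  artefacts whose apparent genotype differs between samples/libraries.
  They are what a recurrent-SNV blacklist exists to catch (~2% of duo
  denominator loci at 1-fold, matching the scale reported for real data),
  and because their relative coverage boost makes them dominate the
  callable set as fold-coverage falls, they reproduce the qualitative
  degradation of the baseline at 0.5-fold. Set
  `systematic_site_fraction = 0` for an artefact-free panel.
- **Reads**: allele sampled uniformly from the individual's two alleles;
  per-read miscall probability 0.005 (typical Q-score-filtered short-read
  error), uniform over the three wrong bases.

All draws flow from `numpy` Generators seeded from the config
(`SeedSequence.spawn` for cohorts), so identical configurations are
bit-reproducible.

**What the simulator does not model:** read-level effects (FASTQ, mapping
bias, duplicates), contamination/mosaicism, linkage disequilibrium between
panel loci, de novo mutation, and the platform-specific error processes that
put the real-data biological baseline near 18% at 1-fold. Simulated
baselines are a few percent, so passing tests demonstrate the *ordering and
separation* structure (biological ≪ non-biological; degradation below
1-fold; exact zero under perfect genotyping) and the correctness of the
arithmetic, not the absolute rate levels of any particular platform —
which is precisely why cutoffs are locally calibrated.

## End-to-end harness and problem sizes

`run_end_to_end` draws one shared panel, simulates `n_calibration`
biological families (each contributing its paternal and maternal rate, so
10 families give the n = 20 baseline design), calibrates trio (Z=3) and duo
(Z=5) models, then classifies `n_biological` + `n_nonbiological` test
families. Verdict recovery compares each verdict with the ground truth
implied by the family structure. The reference cohort (10+10+10 families,
200k loci, 1-fold, 0.5% error) runs in ~10 s on one core; the depth-
monotonicity property is evaluated as the mean over 24 seeded replicates
per fold-coverage. Note the trio Z=3 rule has an inherent few-percent
chance per cohort that one biological rate grazes the cutoff — an operating
characteristic of the mean+3·SD design itself, visible in real and
simulated data alike.

## Numerical and degenerate-input choices

- Pileup parsing validates that the base string encodes exactly the depth
  column's number of read slots after indel stripping; mismatches are
  reported with the 1-based line number.
- Down-sampling thins every read (counted or not) independently with the
  retention probability, recomputes depth, and drops zero-depth loci;
  fraction 1.0 is an exact identity.
- Empty genotype tables, empty blacklists and zero-denominator duos are
  legal and yield empty/ inconclusive results, never exceptions.
- `calibrate_cutoff` refuses fewer than two rates; `cohort_summary` refuses
  empty cohorts; a genotype table refuses duplicated loci, naming the locus.
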