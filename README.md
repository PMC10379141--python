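# lpparentage

Rapid paternity/maternity testing from **low-pass genome sequencing** (~1-fold
read-depth) pileup data.

Clinical trio-based genetic diagnosis assumes the submitted parents are the
biological parents; a misattributed parent (non-paternity, oocyte donation,
sample mix-up) can derail variant interpretation. Low-pass genome sequencing
is already widely used for structural-variant detection, but at ~1-fold depth
conventional genotyping of pre-selected markers is unreliable. This package
implements a genome-wide alternative for laboratories running low-pass GS:
it is aimed at clinical bioinformaticians who have `samtools mpileup` output
in hand and want a parentage QC verdict in minutes.

## Method

At each locus with 5–20 covering reads, a genotype is called from the read
base types: homozygous if 100% of reads support one base (mutant calls
additionally need ≥3 supporting reads), heterozygous if the mutant-base
fraction lies in [0.25, 0.75]; anything else is left uncalled.

Two modes share one decision statistic, the **inconsistent rate of base-type
inheritance**:

- **Trio mode** — informative loci are those where the two presumed parents
  are homozygous for different alleles (e.g. father AA, mother TT): a
  biological child must be heterozygous. The rate is the fraction of
  informative loci where the proband is homozygous with an allele differing
  from the tested parent's.
- **Duo mode** — loci where proband and the single presumed parent are both
  homozygous; opposing homozygotes are impossible under biological parentage
  absent error, and their fraction is the rate.

Because genotyping at 1-fold is error-prone, the rate has a nonzero baseline
even in confirmed-biological families. The reporting cutoff is therefore
calibrated empirically as `mean + Z·SD` over confirmed-biological baseline
rates (Z = 3 trio, Z = 5 duo); rates at or above the cutoff are reported as
*not confirmed*. Shipped defaults are 24.5% (trio) and 25.6% (duo); local
recalibration is recommended and supported. Loci flagged as inconsistent in
more than one analysis are accumulated into a recurrent-SNV blacklist
(systematic alignment errors) and filtered from future tests.

A bundled simulator generates Hardy–Weinberg trios, Mendelian transmission,
parent-substituted non-biological families, and low-pass read sampling with
shared coverage inhomogeneity and systematic-error sites, so the whole
pipeline is testable end to end with no external data (see
`docs/methods.md`).

## Worked example

Simulate a family in which the presumed mother is not the biological mother,
sequenced at 1-fold, then genotype and test it:

```bash
lpparentage simulate --structure nonbiological_mother --depth 1.0 \
    --n-loci 200000 --seed 7 -o fam/
for m in father mother child; do
    lpparentage genotype -i fam/$m.pileup -o fam/$m.tsv --sample-id $m
done
lpparentage trio -p fam/child.tsv -f fam/father.tsv -m fam/mother.tsv
```

Output (abridged):

```json
{
 "paternity": {
  "informative_loci": 246, "inconsistent_loci": 12,
  "rate_percent": 4.88, "verdict": "biological", "cutoff_percent": 24.5
 },
 "maternity": {
  "informative_loci": 246, "inconsistent_loci": 134,
  "rate_percent": 54.47, "verdict": "not_confirmed", "cutoff_percent": 24.5
 }
}
```

Of the 246 loci where both presumed parents are opposing homozygotes, the
child's genotype contradicts maternal inheritance at 134 (54.5%, far above
the 24.5% cutoff — maternity not confirmed) but contradicts paternal
inheritance at only 12 (4.9% — consistent with a biological father given the
low-coverage genotyping error baseline).

The shipped cutoffs come from a real-platform baseline; on data with a
different error profile (including this simulator's) calibrate locally with
`lpparentage calibrate --mode duo --z 5 rates.tsv` from confirmed-biological
rates. The Python API does this in one call:

```python
from lpparentage import SimulationConfig, run_end_to_end

cohort = run_end_to_end(SimulationConfig(seed=11))   # 10 cal + 10 bio + 10 swapped
print(cohort.trio_model.cutoff, cohort.duo_model.cutoff)  # 8.54 3.26 (%)
print(cohort.verdict_recovery())                          # 1.0
```

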