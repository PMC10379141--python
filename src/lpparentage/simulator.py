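"""Synthetic trios and low-pass pileup data for end-to-end testing.

The generator reproduces the statistical structure the test relies on,
with no external data:

* a **locus panel** of polymorphic autosomal sites with alternate-allele
  frequencies drawn uniformly from [0.05, 0.5] (the reference base is the
  major allele), a per-locus coverage bias shared by every sample placed
  on the panel, and a small fraction of systematic-error sites;
* **diploid genotypes** under Hardy-Weinberg equilibrium, with the child
  receiving one allele from each parent (Mendelian transmission).
  Non-biological structures replace the father, mother or child with an
  independent Hardy-Weinberg individual after transmission, emulating the
  randomisation of parents across families used to form known
  non-paternity/non-maternity comparisons;
* **read sampling**: per-locus depth is Poisson with rate
  ``mean_depth x coverage_bias``; each read draws one of the individual's
  two alleles uniformly and is miscalled to one of the three other bases
  with probability ``base_error_rate``.

The coverage bias is lognormal (mean 1, sigma ``coverage_bias_sigma``).
It models the mappability/GC coverage inhomogeneity of real short-read
data, which is what leaves a usable number of loci with 5-20 reads at
1-fold average depth; with independent Poisson(1) depths essentially no
locus would be callable in three samples at once.  Systematic-error sites
(default 0.5% of the panel) carry a tenfold coverage bias and present
each sample with an arbitrary apparent allele fraction (Beta-distributed,
concentrated near 0 and 1), emulating alignment artefacts whose apparent
genotype varies between samples; they are the loci a recurrent-SNV
blacklist exists to catch, and they dominate the callable set as average
depth falls below 1-fold.

Everything is driven by ``numpy`` Generators seeded from the config, so
identical configurations reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import blacklist as blacklist_mod
from .calibration import (
    BIOLOGICAL,
    DEFAULT_Z,
    NOT_CONFIRMED,
    BaselineModel,
    calibrate_cutoff,
    classify,
)
from .genotyping import (
    BASES,
    CODE_TO_ZYGOSITY,
    DEFAULT_PARAMS,
    HET,
    HOM_ALT,
    HOM_REF,
    NO_CALL,
    CallingParams,
    SampleGenotypeTable,
    ZYGOSITY_CODES,
    call_genotypes_array,
)
from .inheritance import (
    DEFAULT_MIN_INFORMATIVE,
    DUO,
    MATERNITY,
    PATERNITY,
    TRIO,
    InheritanceResult,
    duo_inconsistent_rate,
    trio_inconsistent_rate,
)
from .pileup_io import PileupRecord

MEMBERS = ("father", "mother", "child")
STRUCTURES = (
    "biological",
    "nonbiological_father",
    "nonbiological_mother",
    "nonbiological_child",
)

_BASE_ARRAY = np.array(BASES)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated family / cohort.

    ``allele_freq`` is either a fixed alternate-allele frequency or a
    (low, high) tuple for a per-locus uniform draw.  ``mean_depth`` is the
    target fold-coverage; ``base_error_rate`` the per-read miscall
    probability (spread uniformly over the three wrong bases).  Setting
    ``coverage_bias_sigma`` or ``systematic_site_fraction`` to 0 disables
    the corresponding mechanism (pure independent Poisson depths,
    artefact-free panel).
    """

    n_loci: int = 200_000
    allele_freq: float | tuple[float, float] = (0.05, 0.5)
    mean_depth: float = 1.0
    base_error_rate: float = 0.005
    seed: int = 0
    family_structure: str = "biological"
    coverage_bias_sigma: float = 1.5
    systematic_site_fraction: float = 0.005
    systematic_bias_multiplier: float = 10.0
    systematic_beta_concentration: float = 0.3

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        freqs = (
            self.allele_freq
            if isinstance(self.allele_freq, tuple)
            else (self.allele_freq,)
        )
        if any(not 0.0 <= f < 1.0 for f in freqs):
            raise ValueError("allele frequencies must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ValueError("base_error_rate must be in [0, 1)")
        if self.family_structure not in STRUCTURES:
            raise ValueError(f"unknown family_structure {self.family_structure!r}")
        if self.coverage_bias_sigma < 0:
            raise ValueError("coverage_bias_sigma must be >= 0")
        if not 0.0 <= self.systematic_site_fraction < 1.0:
            raise ValueError("systematic_site_fraction must be in [0, 1)")


@dataclass(frozen=True)
class LocusPanel:
    """Genome-side state shared by every sample simulated on it."""

    chrom: np.ndarray  # str per locus
    pos: np.ndarray  # int, 1-based
    ref_idx: np.ndarray  # column into BASES
    alt_idx: np.ndarray
    allele_freq: np.ndarray  # alternate-allele frequency
    coverage_bias: np.ndarray  # multiplies mean_depth in the Poisson rate
    is_systematic: np.ndarray  # bool

    @property
    def n_loci(self) -> int:
        return len(self.pos)


@dataclass(frozen=True)
class TrueGenotypes:
    """Ground-truth diploid genotypes for one family on a panel.

    Genotypes are stored as (n_loci, 2) arrays of 0/1 allele indicators
    (0 = reference, 1 = alternate allele).
    """

    panel: LocusPanel
    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    family_structure: str = "biological"

    def alt_copies(self, member: str) -> np.ndarray:
        """Alternate-allele dosage (0/1/2) per locus for one member."""
        return getattr(self, _check_member(member)).sum(axis=1)


def _check_member(member: str) -> str:
    if member not in MEMBERS:
        raise ValueError(f"member must be one of {MEMBERS}, got {member!r}")
    return member


def make_locus_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> LocusPanel:
    """Draw the shared locus panel implied by a configuration.

    Loci are spread over autosomes 1-22 at increasing positions; allele
    frequencies, coverage biases and systematic-site flags are drawn once
    and reused for every sample on the panel.
    """
    rng = np.random.default_rng([config.seed, 0]) if rng is None else rng
    n = config.n_loci
    idx = np.arange(n)
    chrom_no = 1 + (idx * 22) // n
    starts = np.searchsorted(chrom_no, np.arange(1, 23))
    pos = 10_000 + (idx - starts[chrom_no - 1]) * 1_500
    chrom = np.char.add("chr", chrom_no.astype(str))

    if isinstance(config.allele_freq, tuple):
        lo, hi = config.allele_freq
        freq = rng.uniform(lo, hi, n)
    else:
        freq = np.full(n, float(config.allele_freq))

    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4  # any base but the reference

    if config.coverage_bias_sigma > 0:
        sigma = config.coverage_bias_sigma
        bias = rng.lognormal(-0.5 * sigma**2, sigma, n)
    else:
        bias = np.ones(n)
    is_sys = (
        rng.random(n) < config.systematic_site_fraction
        if config.systematic_site_fraction > 0
        else np.zeros(n, dtype=bool)
    )
    bias = np.where(is_sys, bias * config.systematic_bias_multiplier, bias)
    return LocusPanel(chrom, pos, ref_idx, alt_idx, freq, bias, is_sys)


def _hw_individual(rng: np.random.Generator, freq: np.ndarray) -> np.ndarray:
    """One Hardy-Weinberg diploid: two independent Bernoulli(freq) alleles."""
    return (rng.random((len(freq), 2)) < freq[:, None]).astype(np.int8)


def simulate_trio_genotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    panel: LocusPanel | None = None,
) -> TrueGenotypes:
    """Draw a family's true genotypes under the configured structure.

    Parents are Hardy-Weinberg draws at each locus's allele frequency; the
    child receives one uniformly chosen allele from each parent.  For the
    nonbiological_* structures the named member is then replaced by an
    independent Hardy-Weinberg individual, so e.g. a nonbiological_father
    family keeps the true mother-child link intact.
    """
    rng = np.random.default_rng([config.seed, 1]) if rng is None else rng
    if panel is None:
        panel = make_locus_panel(config, np.random.default_rng([config.seed, 0]))
    n = panel.n_loci
    freq = panel.allele_freq
    father = _hw_individual(rng, freq)
    mother = _hw_individual(rng, freq)
    rows = np.arange(n)
    child = np.stack(
        [
            father[rows, rng.integers(0, 2, n)],
            mother[rows, rng.integers(0, 2, n)],
        ],
        axis=1,
    ).astype(np.int8)
    if config.family_structure == "nonbiological_father":
        father = _hw_individual(rng, freq)
    elif config.family_structure == "nonbiological_mother":
        mother = _hw_individual(rng, freq)
    elif config.family_structure == "nonbiological_child":
        child = _hw_individual(rng, freq)
    return TrueGenotypes(panel, father, mother, child, config.family_structure)


def _scatter_errors(
    rng: np.random.Generator,
    counts: np.ndarray,
    origin_idx: np.ndarray,
    n_errors: np.ndarray,
) -> None:
    """Move ``n_errors`` reads from their origin base to the other three,
    uniformly, in place."""
    others = np.array(
        [[j for j in range(4) if j != o] for o in range(4)]
    )  # (4, 3) complement table
    target = others[origin_idx]  # (n, 3)
    m1 = rng.binomial(n_errors, 1.0 / 3.0)
    m2 = rng.binomial(n_errors - m1, 0.5)
    m3 = n_errors - m1 - m2
    rows = np.arange(len(n_errors))
    for k, mk in enumerate((m1, m2, m3)):
        np.add.at(counts, (rows, target[:, k]), mk)


def simulate_read_counts(
    truth: TrueGenotypes,
    member: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Low-pass read sampling for one family member.

    Returns an (n_loci, 4) matrix of per-base read counts.  Depth is
    Poisson(mean_depth x coverage_bias); allele sampling is binomial on
    the member's alternate-allele dosage; sequencing errors move reads to
    a uniformly chosen wrong base.  At systematic-error sites the apparent
    alternate-read fraction is instead drawn per site and sample from
    Beta(c, c), detached from the true genotype.
    """
    panel = truth.panel
    n = panel.n_loci
    depth = rng.poisson(config.mean_depth * panel.coverage_bias)
    theta = truth.alt_copies(member) / 2.0
    if panel.is_systematic.any():
        c = config.systematic_beta_concentration
        theta = np.where(
            panel.is_systematic, rng.beta(c, c, n), theta
        )
    n_alt = rng.binomial(depth, theta)
    n_ref = depth - n_alt

    counts = np.zeros((n, 4), dtype=np.int64)
    err = config.base_error_rate
    for origin_idx, n_reads in ((panel.ref_idx, n_ref), (panel.alt_idx, n_alt)):
        if err > 0:
            n_err = rng.binomial(n_reads, err)
        else:
            n_err = np.zeros(n, dtype=np.int64)
        np.add.at(counts, (np.arange(n), origin_idx), n_reads - n_err)
        if err > 0:
            _scatter_errors(rng, counts, origin_idx, n_err)
    return counts


def simulate_pileup(
    truth: TrueGenotypes,
    member: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[PileupRecord]:
    """Render one member's reads as pileup records (zero-depth loci omitted)."""
    rng = (
        np.random.default_rng([config.seed, 2 + MEMBERS.index(_check_member(member))])
        if rng is None
        else rng
    )
    counts = simulate_read_counts(truth, member, config, rng)
    panel = truth.panel
    depth = counts.sum(axis=1)
    records = []
    for i in np.flatnonzero(depth):
        base_counts = {
            BASES[j]: int(counts[i, j]) for j in range(4) if counts[i, j]
        }
        records.append(
            PileupRecord(
                str(panel.chrom[i]),
                int(panel.pos[i]),
                BASES[panel.ref_idx[i]],
                int(depth[i]),
                base_counts,
            )
        )
    return records


def _table_from_arrays(
    panel: LocusPanel,
    called: dict[str, np.ndarray],
    sample_id: str,
) -> SampleGenotypeTable:
    zyg = called["zygosity"]
    keep = zyg != ZYGOSITY_CODES[NO_CALL]
    ref_b = _BASE_ARRAY[panel.ref_idx[keep]]
    alt_b = _BASE_ARRAY[called["alt_idx"][keep]]
    zyg_k = zyg[keep]
    allele1 = np.where(zyg_k == ZYGOSITY_CODES[HOM_ALT], alt_b, ref_b)
    allele2 = np.where(zyg_k == ZYGOSITY_CODES[HOM_REF], ref_b, alt_b)
    df = pd.DataFrame(
        {
            "chrom": panel.chrom[keep],
            "pos": panel.pos[keep],
            "ref": ref_b,
            "allele1": allele1,
            "allele2": allele2,
            "zygosity": pd.Series(zyg_k).map(CODE_TO_ZYGOSITY).to_numpy(),
            "depth": called["depth"][keep],
            "alt_count": called["alt_count"][keep],
        }
    )
    return SampleGenotypeTable(sample_id, df)


def genotype_member(
    truth: TrueGenotypes,
    member: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    params: CallingParams = DEFAULT_PARAMS,
) -> SampleGenotypeTable:
    """Simulate reads for one member and genotype them (vectorised path)."""
    counts = simulate_read_counts(truth, _check_member(member), config, rng)
    called = call_genotypes_array(counts, truth.panel.ref_idx, params)
    return _table_from_arrays(truth.panel, called, member)


def genotypes_from_truth(truth: TrueGenotypes, member: str) -> SampleGenotypeTable:
    """Perfect-genotyping table straight from the true diploid genotypes.

    Used for analytic oracles: every locus is 'called' with a nominal
    valid depth and no error, so inheritance statistics reflect the
    genotype model alone.
    """
    panel = truth.panel
    dosage = truth.alt_copies(_check_member(member))
    zyg_code = np.select(
        [dosage == 0, dosage == 1, dosage == 2],
        [ZYGOSITY_CODES[HOM_REF], ZYGOSITY_CODES[HET], ZYGOSITY_CODES[HOM_ALT]],
    ).astype(np.int8)
    called = {
        "zygosity": zyg_code,
        "alt_idx": panel.alt_idx,
        "depth": np.full(panel.n_loci, 10),
        "alt_count": dosage * 5,
    }
    return _table_from_arrays(panel, called, member)


# ---------------------------------------------------------------------------
# end-to-end cohort harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyOutcome:
    """All four comparisons for one family, with verdicts."""

    family_id: str
    structure: str
    results: dict[tuple[str, str], InheritanceResult]  # (mode, relationship)
    verdicts: dict[tuple[str, str], str]

    def expected_verdict(self, mode: str, relationship: str) -> str:
        """Ground-truth verdict implied by the family structure."""
        bad = {
            "nonbiological_father": {PATERNITY},
            "nonbiological_mother": {MATERNITY},
            "nonbiological_child": {PATERNITY, MATERNITY},
        }.get(self.structure, set())
        return NOT_CONFIRMED if relationship in bad else BIOLOGICAL


@dataclass(frozen=True)
class CohortResult:
    """Calibration models plus per-family outcomes of a simulated cohort."""

    trio_model: BaselineModel
    duo_model: BaselineModel
    families: tuple[FamilyOutcome, ...]

    def verdict_recovery(self) -> float:
        """Fraction of comparisons whose verdict matches the ground truth."""
        total = correct = 0
        for fam in self.families:
            for (mode, rel), verdict in fam.verdicts.items():
                total += 1
                correct += verdict == fam.expected_verdict(mode, rel)
        return correct / total if total else float("nan")

    def rates(self, mode: str, structure: str | None = None) -> list[float]:
        """Collect rate_percent values, optionally by family structure."""
        out = []
        for fam in self.families:
            if structure is not None and fam.structure != structure:
                continue
            for (m, _), res in fam.results.items():
                if m == mode and not res.inconclusive:
                    out.append(res.rate_percent)
        return out


def _family_results(
    truth: TrueGenotypes,
    config: SimulationConfig,
    rng: np.random.Generator,
    params: CallingParams,
    min_informative: int,
    blacklist: blacklist_mod.Blacklist | None = None,
) -> dict[tuple[str, str], InheritanceResult]:
    tables = {
        m: genotype_member(truth, m, config, rng, params) for m in MEMBERS
    }
    return {
        (TRIO, PATERNITY): trio_inconsistent_rate(
            tables["child"], tables["father"], tables["mother"], "father",
            blacklist=blacklist, min_informative=min_informative,
        ),
        (TRIO, MATERNITY): trio_inconsistent_rate(
            tables["child"], tables["father"], tables["mother"], "mother",
            blacklist=blacklist, min_informative=min_informative,
        ),
        (DUO, PATERNITY): duo_inconsistent_rate(
            tables["child"], tables["father"], PATERNITY,
            blacklist=blacklist, min_informative=min_informative,
        ),
        (DUO, MATERNITY): duo_inconsistent_rate(
            tables["child"], tables["mother"], MATERNITY,
            blacklist=blacklist, min_informative=min_informative,
        ),
    }


def run_end_to_end(
    config: SimulationConfig | None = None,
    n_calibration: int = 10,
    n_biological: int = 10,
    n_nonbiological: int = 10,
    nonbiological_structures: Sequence[str] = (
        "nonbiological_father",
        "nonbiological_mother",
    ),
    params: CallingParams = DEFAULT_PARAMS,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    blacklist: blacklist_mod.Blacklist | None = None,
) -> CohortResult:
    """Simulate, genotype, test, calibrate and classify a whole cohort.

    A shared locus panel is drawn from ``config``; ``n_calibration``
    confirmed-biological families provide the baseline rates (each family
    contributes its paternal and maternal rate to the mode's baseline,
    mirroring a 2-rates-per-trio calibration set), then ``n_biological``
    biological and ``n_nonbiological`` non-biological test families are
    classified against the calibrated cutoffs (trio Z=3, duo Z=5).  Fully
    deterministic in ``config.seed``.
    """
    config = SimulationConfig() if config is None else config
    seeds = np.random.SeedSequence(config.seed).spawn(
        1 + n_calibration + n_biological + n_nonbiological
    )
    panel = make_locus_panel(config, np.random.default_rng(seeds[0]))

    def one_family(structure: str, seed_seq, fam_id: str):
        rng = np.random.default_rng(seed_seq)
        fam_config = replace(config, family_structure=structure)
        truth = simulate_trio_genotypes(fam_config, rng, panel)
        results = _family_results(
            truth, fam_config, rng, params, min_informative, blacklist
        )
        return fam_id, structure, results

    cal_trio_rates: list[float] = []
    cal_duo_rates: list[float] = []
    for i in range(n_calibration):
        _, _, results = one_family("biological", seeds[1 + i], f"cal{i}")
        for (mode, _), res in results.items():
            if res.inconclusive:
                raise RuntimeError(
                    "calibration family produced an inconclusive result; "
                    "increase n_loci or lower min_informative"
                )
            (cal_trio_rates if mode == TRIO else cal_duo_rates).append(
                res.rate_percent
            )
    trio_model = calibrate_cutoff(cal_trio_rates, DEFAULT_Z[TRIO], mode=TRIO)
    duo_model = calibrate_cutoff(cal_duo_rates, DEFAULT_Z[DUO], mode=DUO)

    families = []
    structures = ["biological"] * n_biological + [
        nonbiological_structures[i % len(nonbiological_structures)]
        for i in range(n_nonbiological)
    ]
    for i, structure in enumerate(structures):
        fam_id, structure, results = one_family(
            structure, seeds[1 + n_calibration + i], f"fam{i}"
        )
        verdicts = {
            key: classify(res, trio_model if key[0] == TRIO else duo_model)
            for key, res in results.items()
        }
        families.append(FamilyOutcome(fam_id, structure, results, verdicts))
    return CohortResult(trio_model, duo_model, tuple(families))
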