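"""Low-pass genotype calling from per-locus read counts.

At ~1-fold coverage, conventional likelihood-based callers are starved of
evidence, so calling is rule-based over a narrow depth window: a locus is
callable only with 5-20 single-base reads (fewer is uninformative, more
indicates collapsed repeats / mapping artefacts), a mutant base needs at
least 3 supporting reads, a homozygous alternate call requires 100% mutant
reads and a heterozygous call a mutant fraction within [0.25, 0.75].
Fractions in the gaps (0, 0.25) and (0.75, 1) are left uncalled, as are
loci with credible support for two different mutant bases (the model is
diploid and biallelic).  Loci with 5-20 reads and zero mismatches are
called homozygous-reference: the trio analysis needs parental genotypes at
sites where a parent simply matches the reference.

Fraction bounds are evaluated with integer arithmetic (``4*alt >= depth``
etc.) so boundary reads are never lost to floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .pileup_io import BASES, PileupRecord

HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
NO_CALL = "no_call"

#: integer codes used on the vectorised path (-1 = no_call)
ZYGOSITY_CODES = {NO_CALL: -1, HOM_REF: 0, HET: 1, HOM_ALT: 2}
CODE_TO_ZYGOSITY = {v: k for k, v in ZYGOSITY_CODES.items()}

#: default autosomal analysis set; sex chromosomes are hemizygous in males
#: and break the diploid genotype bands
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + tuple(
    str(i) for i in range(1, 23)
)


class DuplicateLocusError(ValueError):
    """The same (chrom, pos) appeared twice in one sample's input."""


@dataclass(frozen=True)
class CallingParams:
    """Tunable thresholds of the genotype-calling rule table."""

    min_depth: int = 5
    max_depth: int = 20
    min_alt_reads: int = 3
    het_low: float = 0.25
    het_high: float = 0.75

    def __post_init__(self) -> None:
        if self.min_depth < 1 or self.max_depth < self.min_depth:
            raise ValueError("need 1 <= min_depth <= max_depth")
        if self.min_alt_reads < 1:
            raise ValueError("min_alt_reads must be positive")
        if not 0 < self.het_low < self.het_high <= 1:
            raise ValueError("need 0 < het_low < het_high <= 1")


DEFAULT_PARAMS = CallingParams()


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's zygosity decision at one locus with its evidence."""

    chrom: str
    pos: int
    ref_base: str
    allele_1: str
    allele_2: str
    zygosity: str
    depth: int
    alt_count: int

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def is_homozygous(self) -> bool:
        return self.zygosity in (HOM_REF, HOM_ALT)


def call_genotype(
    record: PileupRecord, params: CallingParams = DEFAULT_PARAMS
) -> GenotypeCall:
    """Apply the rule table to one pileup record.

    The depth window is applied to the counted A/C/G/T reads (reads
    carrying indels or N give no single-base evidence).  The mutant base is
    the highest-count non-reference base; a second non-reference base with
    credible support, or a tie at the top, voids the call.
    """
    ref = record.ref_base.upper()
    depth = record.counted_depth
    nonref = sorted(
        ((record.base_counts.get(b, 0), b) for b in BASES if b != ref),
        reverse=True,
    )
    c1, alt = nonref[0]
    c2 = nonref[1][0] if len(nonref) > 1 else 0

    def no_call() -> GenotypeCall:
        return GenotypeCall(
            record.chrom, record.pos, ref, "N", "N", NO_CALL, depth, c1
        )

    if not params.min_depth <= depth <= params.max_depth:
        return no_call()
    if c1 == 0:
        return GenotypeCall(
            record.chrom, record.pos, ref, ref, ref, HOM_REF, depth, 0
        )
    if c1 < params.min_alt_reads or c2 >= params.min_alt_reads or c1 == c2:
        return no_call()
    if c1 == depth:
        return GenotypeCall(
            record.chrom, record.pos, ref, alt, alt, HOM_ALT, depth, c1
        )
    # integer form of het_low <= c1/depth <= het_high for the default 1/4, 3/4
    lo_num, lo_den = params.het_low.as_integer_ratio()
    hi_num, hi_den = params.het_high.as_integer_ratio()
    if c1 * lo_den >= lo_num * depth and c1 * hi_den <= hi_num * depth:
        return GenotypeCall(
            record.chrom, record.pos, ref, ref, alt, HET, depth, c1
        )
    return no_call()


def call_genotypes_array(
    counts: np.ndarray,
    ref_idx: np.ndarray,
    params: CallingParams = DEFAULT_PARAMS,
) -> dict[str, np.ndarray]:
    """Vectorised rule table over an (n, 4) count matrix.

    ``counts[:, j]`` is the read count for base ``BASES[j]``; ``ref_idx``
    holds the reference-base column per locus.  Returns integer zygosity
    codes (see :data:`ZYGOSITY_CODES`), the mutant-base column, depth and
    mutant read count.  Semantically identical to :func:`call_genotype`
    applied row-wise.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[0]
    rows = np.arange(n)
    depth = counts.sum(axis=1)

    masked = counts.copy()
    masked[rows, ref_idx] = -1  # exclude the reference column
    alt_idx = masked.argmax(axis=1)
    c1 = masked[rows, alt_idx]
    masked[rows, alt_idx] = -1
    c2 = masked.max(axis=1)
    c2 = np.maximum(c2, 0)

    zyg = np.full(n, ZYGOSITY_CODES[NO_CALL], dtype=np.int8)
    in_window = (depth >= params.min_depth) & (depth <= params.max_depth)
    zyg[in_window & (c1 == 0)] = ZYGOSITY_CODES[HOM_REF]
    valid_alt = (
        in_window
        & (c1 >= params.min_alt_reads)
        & (c2 < params.min_alt_reads)
        & (c1 != c2)
    )
    zyg[valid_alt & (c1 == depth)] = ZYGOSITY_CODES[HOM_ALT]
    lo_num, lo_den = params.het_low.as_integer_ratio()
    hi_num, hi_den = params.het_high.as_integer_ratio()
    het = (
        valid_alt
        & (c1 < depth)
        & (c1 * lo_den >= lo_num * depth)
        & (c1 * hi_den <= hi_num * depth)
    )
    zyg[het] = ZYGOSITY_CODES[HET]
    return {"zygosity": zyg, "alt_idx": alt_idx, "depth": depth, "alt_count": c1}


_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "allele1",
    "allele2",
    "zygosity",
    "depth",
    "alt_count",
]


@dataclass
class SampleGenotypeTable:
    """All callable loci for one sample, keyed by (chrom, pos).

    Backed by a DataFrame with columns chrom, pos, ref, allele1, allele2,
    zygosity, depth, alt_count; only non-no_call loci are stored, one row
    per locus.
    """

    sample_id: str
    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_TABLE_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = set(_TABLE_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"genotype table missing columns: {sorted(missing)}")
        dup = self.df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = self.df[dup].iloc[0]
            raise DuplicateLocusError(
                f"duplicate locus {row['chrom']}:{row['pos']} "
                f"in sample {self.sample_id}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def loci(self) -> set[tuple[str, int]]:
        return set(zip(self.df["chrom"], self.df["pos"]))

    def to_tsv(self, dest: str | IO[str]) -> None:
        self.df.to_csv(dest, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, source: str | IO[str], sample_id: str) -> "SampleGenotypeTable":
        df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
        return cls(sample_id, df)

    @classmethod
    def from_calls(
        cls, calls: Iterable[GenotypeCall], sample_id: str
    ) -> "SampleGenotypeTable":
        rows = [
            (c.chrom, c.pos, c.ref_base, c.allele_1, c.allele_2, c.zygosity,
             c.depth, c.alt_count)
            for c in calls
            if c.zygosity != NO_CALL
        ]
        df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
        return cls(sample_id, df)


def genotype_sample(
    records: Iterable[PileupRecord],
    sample_id: str,
    params: CallingParams = DEFAULT_PARAMS,
    chroms: Iterable[str] | None = AUTOSOMES,
) -> SampleGenotypeTable:
    """Call genotypes over one sample's pileup records.

    Keeps every non-no_call locus; a duplicated (chrom, pos) raises
    :class:`DuplicateLocusError`.  ``chroms`` defaults to autosomes 1-22
    (accepting both ``chr1`` and ``1`` spellings); pass None to disable the
    restriction.
    """
    chrom_set = set(chroms) if chroms is not None else None
    seen: set[tuple[str, int]] = set()
    calls = []
    for record in records:
        if chrom_set is not None and record.chrom not in chrom_set:
            continue
        key = (record.chrom, record.pos)
        if key in seen:
            raise DuplicateLocusError(
                f"duplicate locus {record.chrom}:{record.pos} "
                f"in sample {sample_id}"
            )
        seen.add(key)
        call = call_genotype(record, params)
        if call.zygosity != NO_CALL:
            calls.append(call)
    return SampleGenotypeTable.from_calls(calls, sample_id)
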