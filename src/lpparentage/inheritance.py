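"""Informative-locus selection and inconsistent rates of base-type inheritance.

Two analytical modes share one decision statistic:

* **trio mode** — loci where both presumed parents are homozygous for
  different alleles are informative; a biological child must be
  heterozygous there, so the fraction of informative loci at which the
  proband is homozygous with an allele differing from the tested parent's
  is the "inconsistent rate" of paternal (or maternal) inheritance.
* **duo mode** — loci where proband and the single presumed parent are
  both homozygous; opposing homozygotes (different alleles) are impossible
  under biological parentage absent genotyping error, so their fraction is
  the duo inconsistent rate.

Proband-heterozygous loci carrying an allele seen in neither parent are a
genotyping-error signature; they are reported as a diagnostic count but
excluded from the numerator.  Loci in a systematic-error blacklist are
removed before either count.  A denominator below ``min_informative``
yields an inconclusive result rather than a rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .blacklist import Blacklist
from .genotyping import HET, HOM_ALT, HOM_REF, SampleGenotypeTable

TRIO = "trio"
DUO = "duo"
PATERNITY = "paternity"
MATERNITY = "maternity"

#: below this many informative loci the rate is not reported
DEFAULT_MIN_INFORMATIVE = 100


@dataclass(frozen=True)
class InheritanceResult:
    """Outcome of one paternity or maternity comparison."""

    mode: str
    relationship_tested: str
    informative_loci: int
    inconsistent_loci: int
    inconsistent_rate: float | None
    flagged_loci: tuple[tuple[str, int], ...] = ()
    het_novel_allele_loci: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.inconsistent_loci <= max(self.informative_loci, 0):
            raise ValueError("inconsistent_loci out of range")

    @property
    def inconclusive(self) -> bool:
        return self.inconsistent_rate is None

    @property
    def rate_percent(self) -> float | None:
        return None if self.inconclusive else 100.0 * self.inconsistent_rate

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "relationship_tested": self.relationship_tested,
            "informative_loci": self.informative_loci,
            "inconsistent_loci": self.inconsistent_loci,
            "rate_percent": self.rate_percent,
            "het_novel_allele_loci": self.het_novel_allele_loci,
            "inconclusive": self.inconclusive,
        }


def apply_blacklist(
    loci: Sequence[tuple[str, int]] | pd.DataFrame,
    blacklist: Blacklist | None,
) -> Sequence[tuple[str, int]] | pd.DataFrame:
    """Drop loci curated as recurrent systematic errors.

    Accepts either a list of (chrom, pos) pairs or a DataFrame with chrom
    and pos columns; returns the same kind with blacklisted loci removed.
    """
    if blacklist is None or not len(blacklist):
        return loci
    bad = blacklist.recurrent_loci()
    if isinstance(loci, pd.DataFrame):
        keys = list(zip(loci["chrom"], loci["pos"]))
        keep = [k not in bad for k in keys]
        return loci[keep]
    return [locus for locus in loci if locus not in bad]


def _hom_table(table: SampleGenotypeTable, prefix: str) -> pd.DataFrame:
    df = table.df
    hom = df[df["zygosity"].isin((HOM_REF, HOM_ALT))]
    return hom[["chrom", "pos", "allele1"]].rename(
        columns={"allele1": f"{prefix}_allele"}
    )


def select_trio_informative_loci(
    proband: SampleGenotypeTable,
    father: SampleGenotypeTable,
    mother: SampleGenotypeTable,
    require_proband_call: bool = True,
) -> pd.DataFrame:
    """Loci where both parents are homozygous for different alleles.

    Returns a DataFrame with one row per informative locus: chrom, pos,
    father_allele, mother_allele, and — where the proband has a call —
    proband zygosity and alleles.  With ``require_proband_call`` (default)
    loci lacking a proband call are excluded from the denominator; the
    toggle exists because a denominator padded with uncallable loci would
    deflate the rate with missing data rather than evidence.
    """
    parents = _hom_table(father, "father").merge(
        _hom_table(mother, "mother"), on=["chrom", "pos"], how="inner"
    )
    parents = parents[parents["father_allele"] != parents["mother_allele"]]
    pro = proband.df[["chrom", "pos", "zygosity", "allele1", "allele2"]].rename(
        columns={
            "zygosity": "proband_zygosity",
            "allele1": "proband_allele1",
            "allele2": "proband_allele2",
        }
    )
    how = "inner" if require_proband_call else "left"
    return parents.merge(pro, on=["chrom", "pos"], how=how)


def trio_inconsistent_rate(
    proband: SampleGenotypeTable,
    father: SampleGenotypeTable,
    mother: SampleGenotypeTable,
    tested_parent: str = "father",
    blacklist: Blacklist | None = None,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
    require_proband_call: bool = True,
) -> InheritanceResult:
    """Trio-mode inconsistent rate against the tested parent.

    Numerator: informative loci where the proband is homozygous with an
    allele different from the tested parent's homozygous allele.
    """
    if tested_parent not in ("father", "mother"):
        raise ValueError(f"tested_parent must be father/mother, got {tested_parent}")
    info = select_trio_informative_loci(
        proband, father, mother, require_proband_call=require_proband_call
    )
    info = apply_blacklist(info, blacklist)
    n_informative = len(info)

    pro_hom = info["proband_zygosity"].isin((HOM_REF, HOM_ALT))
    inconsistent = pro_hom & (
        info["proband_allele1"] != info[f"{tested_parent}_allele"]
    )
    pro_het = info["proband_zygosity"] == HET
    in_parents = lambda col: (  # noqa: E731 - tiny local predicate
        (info[col] == info["father_allele"]) | (info[col] == info["mother_allele"])
    )
    het_novel = pro_het & ~(in_parents("proband_allele1") & in_parents("proband_allele2"))

    flagged = tuple(
        zip(info.loc[inconsistent, "chrom"], info.loc[inconsistent, "pos"])
    )
    n_inconsistent = int(inconsistent.sum())
    rate = (
        n_inconsistent / n_informative if n_informative >= max(min_informative, 1) else None
    )
    return InheritanceResult(
        mode=TRIO,
        relationship_tested=PATERNITY if tested_parent == "father" else MATERNITY,
        informative_loci=n_informative,
        inconsistent_loci=n_inconsistent,
        inconsistent_rate=rate,
        flagged_loci=flagged,
        het_novel_allele_loci=int(het_novel.sum()),
    )


def duo_inconsistent_rate(
    proband: SampleGenotypeTable,
    parent: SampleGenotypeTable,
    relationship_tested: str = PATERNITY,
    blacklist: Blacklist | None = None,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> InheritanceResult:
    """Duo-mode inconsistent rate: opposing homozygotes among both-hom loci."""
    if relationship_tested not in (PATERNITY, MATERNITY):
        raise ValueError(
            f"relationship_tested must be paternity/maternity, got {relationship_tested}"
        )
    both = _hom_table(proband, "proband").merge(
        _hom_table(parent, "parent"), on=["chrom", "pos"], how="inner"
    )
    both = apply_blacklist(both, blacklist)
    n_informative = len(both)
    inconsistent = both["proband_allele"] != both["parent_allele"]
    flagged = tuple(
        zip(both.loc[inconsistent, "chrom"], both.loc[inconsistent, "pos"])
    )
    n_inconsistent = int(inconsistent.sum())
    rate = (
        n_inconsistent / n_informative if n_informative >= max(min_informative, 1) else None
    )
    return InheritanceResult(
        mode=DUO,
        relationship_tested=relationship_tested,
        informative_loci=n_informative,
        inconsistent_loci=n_inconsistent,
        inconsistent_rate=rate,
        flagged_loci=flagged,
    )
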