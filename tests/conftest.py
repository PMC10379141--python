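import pandas as pd
import pytest

from lpparentage.genotyping import HET, HOM_ALT, HOM_REF, SampleGenotypeTable


def make_table(sample_id, entries):
    """Build a genotype table from (chrom, pos, ref, genotype) tuples.

    ``genotype`` is a two-letter string like "AA" or "AT"; zygosity is
    derived from the reference base.  Pass None as genotype to omit the
    locus (no call).
    """
    rows = []
    for chrom, pos, ref, gt in entries:
        if gt is None:
            continue
        a1, a2 = gt[0], gt[1]
        if a1 == a2:
            zyg = HOM_REF if a1 == ref else HOM_ALT
            alt_count = 0 if zyg == HOM_REF else 10
        else:
            zyg = HET
            alt_count = 5
        rows.append((chrom, pos, ref, a1, a2, zyg, 10, alt_count))
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "allele1", "allele2", "zygosity",
                 "depth", "alt_count"],
    )
    return SampleGenotypeTable(sample_id, df)


@pytest.fixture
def simple_trio_tables():
    """Four informative loci (father AA, mother TT) with proband
    AT, AT, TT, AT — one paternal inconsistency, no maternal one."""
    loci = [("chr1", p, "A") for p in (100, 200, 300, 400)]
    father = make_table("father", [(c, p, r, "AA") for c, p, r in loci])
    mother = make_table("mother", [(c, p, r, "TT") for c, p, r in loci])
    proband = make_table(
        "proband",
        [(c, p, r, gt) for (c, p, r), gt in zip(loci, ["AT", "AT", "TT", "AT"])],
    )
    return proband, father, mother
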