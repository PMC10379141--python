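import numpy as np
import pytest

from conftest import make_table
from lpparentage.blacklist import Blacklist
from lpparentage.inheritance import (
    DUO,
    MATERNITY,
    apply_blacklist,
    duo_inconsistent_rate,
    select_trio_informative_loci,
    trio_inconsistent_rate,
)


class TestSelectTrioInformativeLoci:
    def test_opposing_homozygous_parents_selected(self):
        father = make_table("f", [("chr1", 100, "A", "AA")])
        mother = make_table("m", [("chr1", 100, "A", "TT")])
        proband = make_table("p", [("chr1", 100, "A", "AT")])
        info = select_trio_informative_loci(proband, father, mother)
        assert list(zip(info["chrom"], info["pos"])) == [("chr1", 100)]

    def test_identical_homozygous_parents_not_selected(self):
        father = make_table("f", [("chr1", 100, "A", "AA")])
        mother = make_table("m", [("chr1", 100, "A", "AA")])
        proband = make_table("p", [("chr1", 100, "A", "AA")])
        assert len(select_trio_informative_loci(proband, father, mother)) == 0

    def test_heterozygous_parent_not_selected(self):
        father = make_table("f", [("chr1", 100, "A", "AT")])
        mother = make_table("m", [("chr1", 100, "A", "TT")])
        proband = make_table("p", [("chr1", 100, "A", "AT")])
        assert len(select_trio_informative_loci(proband, father, mother)) == 0

    def test_proband_no_call_excluded_from_denominator(self):
        father = make_table("f", [("chr1", 100, "A", "AA")])
        mother = make_table("m", [("chr1", 100, "A", "TT")])
        proband = make_table("p", [("chr1", 100, "A", None)])
        assert len(select_trio_informative_loci(proband, father, mother)) == 0
        info = select_trio_informative_loci(
            proband, father, mother, require_proband_call=False
        )
        assert len(info) == 1  # config toggle keeps the locus, uncalled

    def test_two_nonreference_homozygotes_accepted(self):
        father = make_table("f", [("chr1", 100, "A", "GG")])
        mother = make_table("m", [("chr1", 100, "A", "TT")])
        proband = make_table("p", [("chr1", 100, "A", "GT")])
        assert len(select_trio_informative_loci(proband, father, mother)) == 1


class TestTrioInconsistentRate:
    def test_all_heterozygous_proband_gives_zero_rate(self):
        loci = [("chr1", p, "A") for p in range(100, 1100, 100)]
        father = make_table("f", [(c, p, r, "AA") for c, p, r in loci])
        mother = make_table("m", [(c, p, r, "TT") for c, p, r in loci])
        proband = make_table("p", [(c, p, r, "AT") for c, p, r in loci])
        res = trio_inconsistent_rate(proband, father, mother, "father",
                                     min_informative=1)
        assert res.informative_loci == 10
        assert res.inconsistent_rate == 0.0

    def test_hand_counted_rates(self, simple_trio_tables):
        proband, father, mother = simple_trio_tables
        pat = trio_inconsistent_rate(proband, father, mother, "father",
                                     min_informative=1)
        mat = trio_inconsistent_rate(proband, father, mother, "mother",
                                     min_informative=1)
        assert (pat.informative_loci, pat.inconsistent_loci) == (4, 1)
        assert pat.inconsistent_rate == 0.25
        assert mat.inconsistent_rate == 0.0
        assert pat.flagged_loci == (("chr1", 300),)

    def test_hom_matching_mother_counts_against_father(self):
        loci = [("chr1", p, "A") for p in range(100, 600, 100)]
        father = make_table("f", [(c, p, r, "AA") for c, p, r in loci])
        mother = make_table("m", [(c, p, r, "TT") for c, p, r in loci])
        genotypes = ["TT", "TT", "AT", "AT", "AT"]
        proband = make_table(
            "p", [(c, p, r, g) for (c, p, r), g in zip(loci, genotypes)]
        )
        res = trio_inconsistent_rate(proband, father, mother, "father",
                                     min_informative=1)
        assert res.inconsistent_rate == pytest.approx(0.4)

    def test_het_novel_allele_is_diagnostic_not_numerator(self):
        loci = [("chr1", p, "A") for p in range(100, 500, 100)]
        father = make_table("f", [(c, p, r, "AA") for c, p, r in loci])
        mother = make_table("m", [(c, p, r, "TT") for c, p, r in loci])
        genotypes = ["AG", "AT", "AT", "AT"]  # G seen in neither parent
        proband = make_table(
            "p", [(c, p, r, g) for (c, p, r), g in zip(loci, genotypes)]
        )
        res = trio_inconsistent_rate(proband, father, mother, "father",
                                     min_informative=1)
        assert res.het_novel_allele_loci == 1
        assert res.inconsistent_loci == 0

    def test_below_min_informative_is_inconclusive(self, simple_trio_tables):
        proband, father, mother = simple_trio_tables
        res = trio_inconsistent_rate(proband, father, mother, "father",
                                     min_informative=100)
        assert res.inconclusive and res.inconsistent_rate is None

    def test_swapping_parent_labels_swaps_relationships(self):
        rng = np.random.default_rng(4)
        loci = [("chr2", int(p), "C") for p in rng.choice(10**6, 300, replace=False)]
        draw = lambda: [
            (c, p, r, rng.choice(["CC", "GG", "CG"])) for c, p, r in loci
        ]
        father = make_table("f", draw())
        mother = make_table("m", draw())
        proband = make_table("p", draw())
        pat = trio_inconsistent_rate(proband, father, mother, "father",
                                     min_informative=1)
        mat_swapped = trio_inconsistent_rate(proband, mother, father, "mother",
                                             min_informative=1)
        assert pat.informative_loci == mat_swapped.informative_loci
        assert pat.inconsistent_loci == mat_swapped.inconsistent_loci
        assert set(pat.flagged_loci) == set(mat_swapped.flagged_loci)


class TestDuoInconsistentRate:
    def test_identical_homozygotes_give_zero(self):
        loci = [("chr1", p, "A") for p in range(100, 900, 100)]
        parent = make_table("f", [(c, p, r, "AA") for c, p, r in loci])
        proband = make_table("p", [(c, p, r, "AA") for c, p, r in loci])
        res = duo_inconsistent_rate(proband, parent, min_informative=1)
        assert res.informative_loci == 8 and res.inconsistent_rate == 0.0

    def test_opposing_homozygotes_counted(self):
        loci = [("chr1", p, "A") for p in range(100, 700, 100)]
        parent = make_table("f", [(c, p, r, "AA") for c, p, r in loci])
        genotypes = ["AA", "TT", "AA", "TT", "AA", "AA"]
        proband = make_table(
            "p", [(c, p, r, g) for (c, p, r), g in zip(loci, genotypes)]
        )
        res = duo_inconsistent_rate(proband, parent, min_informative=1)
        assert res.informative_loci == 6
        assert res.inconsistent_rate == pytest.approx(1 / 3)

    def test_heterozygous_proband_everywhere_is_inconclusive(self):
        loci = [("chr1", p, "A") for p in range(100, 600, 100)]
        parent = make_table("f", [(c, p, r, "AA") for c, p, r in loci])
        proband = make_table("p", [(c, p, r, "AT") for c, p, r in loci])
        res = duo_inconsistent_rate(proband, parent, min_informative=1)
        assert res.informative_loci == 0 and res.inconclusive

    def test_relationship_label_carried(self):
        loci = [("chr1", 100, "A")]
        parent = make_table("m", [(c, p, r, "AA") for c, p, r in loci])
        proband = make_table("p", [(c, p, r, "AA") for c, p, r in loci])
        res = duo_inconsistent_rate(proband, parent, MATERNITY, min_informative=1)
        assert res.relationship_tested == MATERNITY and res.mode == DUO


class TestApplyBlacklist:
    def test_empty_blacklist_is_identity(self):
        loci = [("chr1", 1), ("chr1", 2)]
        assert apply_blacklist(loci, Blacklist()) == loci
        assert apply_blacklist(loci, None) == loci

    def test_recurrent_loci_removed(self):
        loci = [("chr1", i) for i in range(10)]
        bl = Blacklist({("chr1", 2): 3, ("chr1", 7): 2, ("chr1", 9): 1})
        kept = apply_blacklist(loci, bl)
        # the count-1 locus is not recurrent, so it survives filtering
        assert len(kept) == 8 and ("chr1", 9) in kept

    def test_fully_blacklisted_input_empties(self):
        loci = [("chr1", 1), ("chr1", 2)]
        bl = Blacklist({("chr1", 1): 2, ("chr1", 2): 5})
        assert apply_blacklist(loci, bl) == []

    def test_blacklist_shrinks_trio_denominator(self, simple_trio_tables):
        proband, father, mother = simple_trio_tables
        bl = Blacklist({("chr1", 300): 2})
        res = trio_inconsistent_rate(proband, father, mother, "father",
                                     blacklist=bl, min_informative=1)
        assert res.informative_loci == 3 and res.inconsistent_loci == 0
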