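"""Recurrent-SNV blacklist: curated systematic-error loci.

Shotgun sequencing spreads reads essentially uniformly, so a locus flagged
as inconsistently inherited in many unrelated analyses is far more likely
an alignment/systematic artefact than repeated coincidence.  The blacklist
accumulates flagged loci across analyses, counts in how many analyses each
locus appeared (a locus flagged twice within one analysis still counts
once), and exports those seen at least ``min_recurrence`` times (default
2, i.e. "detected more than once") for exclusion from future tests.
Paternity and maternity tests of the same family count as separate
analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd

Locus = tuple[str, int]


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < chrX."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    return (int(m.group(1)), "") if m else (10**9, chrom)


@dataclass
class Blacklist:
    """Mapping (chrom, pos) -> number of analyses that flagged the locus."""

    entries: dict[Locus, int] = field(default_factory=dict)
    min_recurrence: int = 2

    def __post_init__(self) -> None:
        if self.min_recurrence < 1:
            raise ValueError("min_recurrence must be >= 1")
        if any(c < 1 for c in self.entries.values()):
            raise ValueError("occurrence counts must be >= 1")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, locus: Locus) -> bool:
        return locus in self.entries

    def recurrent_loci(self) -> set[Locus]:
        """Loci meeting the recurrence threshold (the exported/filter set)."""
        return {
            locus for locus, n in self.entries.items() if n >= self.min_recurrence
        }

    def add_analysis(self, flagged_loci: Iterable[Locus]) -> None:
        """Record one analysis; duplicates within it count once."""
        for locus in set(map(tuple, flagged_loci)):
            self.entries[locus] = self.entries.get(locus, 0) + 1

    def merged_with(self, other: "Blacklist") -> "Blacklist":
        """Union of two blacklists, summing per-locus analysis counts."""
        entries = dict(self.entries)
        for locus, n in other.entries.items():
            entries[locus] = entries.get(locus, 0) + n
        return Blacklist(entries, min_recurrence=self.min_recurrence)


def accumulate(
    flagged_loci_per_analysis: Sequence[Iterable[Locus]],
    min_recurrence: int = 2,
) -> Blacklist:
    """Build a blacklist from the flagged-locus lists of several analyses."""
    bl = Blacklist(min_recurrence=min_recurrence)
    for flagged in flagged_loci_per_analysis:
        bl.add_analysis(flagged)
    return bl


def export(blacklist: Blacklist, dest: str | IO[str]) -> pd.DataFrame:
    """Write entries meeting min_recurrence as TSV (chrom, pos, count).

    Rows are sorted by chromosome (natural order) then position; an empty
    blacklist yields a header-only file.  Returns the exported frame.
    """
    rows = [
        (chrom, pos, blacklist.entries[(chrom, pos)])
        for (chrom, pos) in blacklist.recurrent_loci()
    ]
    rows.sort(key=lambda r: (_chrom_sort_key(r[0]), r[1]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "count"])
    df.to_csv(dest, sep="\t", index=False)
    return df


def load(source: str | IO[str], min_recurrence: int = 2) -> Blacklist:
    """Read a blacklist TSV written by :func:`export`."""
    df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    entries = {
        (chrom, int(pos)): int(n)
        for chrom, pos, n in zip(df["chrom"], df["pos"], df["count"])
    }
    return Blacklist(entries, min_recurrence=min_recurrence)
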