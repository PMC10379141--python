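"""Reading, writing and depth-downsampling of samtools-mpileup text records.

The mpileup text dialect summarises aligned reads per genomic position:
``chrom  pos  ref  depth  bases  quals`` with 1-based inclusive coordinates.
The base string encodes one symbol per read: ``.``/``,`` for a reference
match on the forward/reverse strand, upper/lowercase ``ACGT`` for a
mismatch, ``^X`` (read start; ``X`` is a mapping-quality character) and
``$`` (read end) markers, ``+n<seq>``/``-n<seq>`` indel descriptors, ``*``
deletion placeholders and ``>``/``<`` reference skips.

Only single-base evidence matters downstream, so parsing reduces each
record to per-base read counts over {A, C, G, T}: indel descriptors,
deletion placeholders, reference skips and N calls contribute to the depth
column but never to the base counts, and strand case is collapsed.
Quality columns are carried but unused.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np

BASES = ("A", "C", "G", "T")

#: read symbols that occupy a slot in the base string but are never counted
_UNCOUNTED = set("*><Nn")


class PileupParseError(ValueError):
    """Malformed mpileup line; message carries the 1-based line number."""


@dataclass(frozen=True)
class PileupRecord:
    """One sample's read evidence at one genomic position.

    ``base_counts`` maps base type -> read count after parsing the base
    string; reads carrying deletions, skips or N are excluded, so
    ``sum(base_counts.values()) <= depth``.
    """

    chrom: str
    pos: int
    ref_base: str
    depth: int
    base_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.depth < 0:
            raise ValueError(f"depth must be non-negative, got {self.depth}")
        bad = set(self.base_counts) - set(BASES)
        if bad:
            raise ValueError(f"base_counts keys outside A/C/G/T: {sorted(bad)}")
        if sum(self.base_counts.values()) > self.depth:
            raise ValueError(
                f"base_counts sum exceeds depth at {self.chrom}:{self.pos}"
            )

    @property
    def counted_depth(self) -> int:
        """Reads contributing single-base evidence (A/C/G/T only)."""
        return sum(self.base_counts.values())


def _parse_base_string(bases: str, ref_base: str) -> tuple[dict[str, int], int]:
    """Scan an mpileup base string; return (counts, number of read slots)."""
    counts: dict[str, int] = {}
    ref = ref_base.upper()
    n_slots = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # consume the mapping-quality character too
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ValueError(f"indel descriptor without length at offset {i}")
            i = j + int(bases[i + 1 : j])
            if i > n:
                raise ValueError("indel descriptor overruns base string")
        elif c in ".,":
            if ref in BASES:
                counts[ref] = counts.get(ref, 0) + 1
            n_slots += 1
            i += 1
        elif c.upper() in BASES:
            b = c.upper()
            counts[b] = counts.get(b, 0) + 1
            n_slots += 1
            i += 1
        elif c in _UNCOUNTED:
            n_slots += 1
            i += 1
        else:
            raise ValueError(f"unexpected character {c!r} in base string")
    return counts, n_slots


def parse_pileup_line(line: str, line_number: int | None = None) -> PileupRecord:
    """Parse one mpileup text line into a :class:`PileupRecord`.

    Raises :class:`PileupParseError` (naming ``line_number`` when given) on
    fewer than 5 columns, a non-numeric position/depth, or a base string
    whose read slots contradict the depth column after indel stripping.
    """

    def _fail(msg: str) -> PileupParseError:
        where = f" (line {line_number})" if line_number is not None else ""
        return PileupParseError(f"{msg}{where}: {line.rstrip()!r}")

    fields = line.split()
    if len(fields) < 5:
        raise _fail(f"expected >= 5 columns, got {len(fields)}")
    chrom, pos_s, ref_base, depth_s, bases = fields[:5]
    try:
        pos = int(pos_s)
        depth = int(depth_s)
    except ValueError:
        raise _fail("non-integer position or depth") from None
    try:
        counts, n_slots = _parse_base_string(bases, ref_base)
    except ValueError as exc:
        raise _fail(str(exc)) from None
    if n_slots != depth:
        raise _fail(
            f"base string encodes {n_slots} reads but depth column says {depth}"
        )
    try:
        return PileupRecord(chrom, pos, ref_base.upper(), depth, counts)
    except ValueError as exc:
        raise _fail(str(exc)) from None


def _open_text(source: str | IO[str]) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False  # caller owns the handle
    if str(source).endswith(".gz"):
        return gzip.open(source, "rt"), True
    return open(source, "rt"), True


def read_pileup(
    source: str | IO[str] | Iterable[str],
    chroms: set[str] | Sequence[str] | None = None,
) -> Iterator[PileupRecord]:
    """Yield records from a pileup path / stream in input order.

    Empty lines are skipped; parse errors propagate with the 1-based line
    number.  ``chroms`` optionally restricts output to a chromosome set.
    """
    chrom_set = set(chroms) if chroms is not None else None
    handle: IO[str] | Iterable[str]
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        handle, close = _open_text(source)  # type: ignore[arg-type]
    else:
        handle = source
    try:
        for line_number, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            record = parse_pileup_line(line, line_number)
            if chrom_set is not None and record.chrom not in chrom_set:
                continue
            yield record
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]


def format_pileup_record(record: PileupRecord, qual_char: str = "I") -> str:
    """Render a record back to the mpileup dialect.

    Reference-matching reads become ``.``, mismatches their uppercase base,
    and any depth not covered by base counts is emitted as ``*``
    placeholders, so the depth column stays consistent.
    """
    parts: list[str] = []
    ref = record.ref_base.upper()
    for base in BASES:
        count = record.base_counts.get(base, 0)
        if count:
            parts.append(("." if base == ref else base) * count)
    parts.append("*" * (record.depth - record.counted_depth))
    bases = "".join(parts) or "*"
    quals = qual_char * max(record.depth, 1)
    return (
        f"{record.chrom}\t{record.pos}\t{record.ref_base}\t"
        f"{record.depth}\t{bases}\t{quals}"
    )


def write_pileup(records: Iterable[PileupRecord], dest: str | IO[str]) -> None:
    """Write records to a pileup file (gzip if the path ends in .gz)."""
    handle, close = _open_text_write(dest)
    try:
        for record in records:
            handle.write(format_pileup_record(record) + "\n")
    finally:
        if close:
            handle.close()


def _open_text_write(dest: str | IO[str]) -> tuple[IO[str], bool]:
    if hasattr(dest, "write"):
        return dest, False
    if str(dest).endswith(".gz"):
        return gzip.open(dest, "wt"), True
    return open(dest, "wt"), True


def downsample_pileup(
    records: Iterable[PileupRecord], fraction: float, seed: int
) -> list[PileupRecord]:
    """Binomially thin every read with retention probability ``fraction``.

    Emulates sequencing the library to a lower fold-coverage: each read at
    each locus is kept independently, depth is recomputed, and loci left
    with zero reads are dropped.  Deterministic in (records, fraction,
    seed).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    out: list[PileupRecord] = []
    for record in records:
        kept: dict[str, int] = {}
        for base in BASES:
            count = record.base_counts.get(base, 0)
            if count:
                k = int(rng.binomial(count, fraction))
                if k:
                    kept[base] = k
        uncounted = record.depth - record.counted_depth
        kept_uncounted = int(rng.binomial(uncounted, fraction)) if uncounted else 0
        new_depth = sum(kept.values()) + kept_uncounted
        if new_depth == 0:
            continue
        out.append(
            PileupRecord(record.chrom, record.pos, record.ref_base, new_depth, kept)
        )
    return out
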