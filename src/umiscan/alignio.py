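"""Alignment and interval I/O plus column/coordinate bookkeeping.

Internal conventions
--------------------
* Coordinates are 0-based half-open on the ``+`` strand of each species.
  AXT (1-based inclusive) and MAF (0-based, strand-relative) are converted at
  the parsing boundary; the original strand is retained for reporting.
* ``N`` is never counted as a match downstream; regions that are mostly N are
  the caller's problem to skip (see :func:`umiscan.diffscan.find_difference_events`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, TextIO, Union

import pandas as pd
from Bio import AlignIO, SeqIO

_VALID_CHARS = set("ACGTN-")


class ParseError(ValueError):
    """Malformed input; the message names the offending block/record."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GappedPair:
    """One pairwise local alignment: two equal-length gapped texts plus coordinates.

    The unit scanned for inversions.  ``text_a``/``text_b`` are uppercase strings
    over ``ACGTN-``; no column may be a gap in both rows.
    """

    text_a: str
    text_b: str
    loc_a: GenomicInterval
    loc_b: GenomicInterval
    id: str = ""

    def __post_init__(self) -> None:
        self.text_a = self.text_a.upper()
        self.text_b = self.text_b.upper()
        if len(self.text_a) != len(self.text_b):
            raise ValueError(f"pair {self.id!r}: row lengths differ")
        bad = (set(self.text_a) | set(self.text_b)) - _VALID_CHARS
        if bad:
            raise ValueError(f"pair {self.id!r}: invalid characters {sorted(bad)}")
        for which, text, loc in (("a", self.text_a, self.loc_a), ("b", self.text_b, self.loc_b)):
            ungapped = len(text) - text.count("-")
            if ungapped != len(loc):
                raise ValueError(
                    f"pair {self.id!r}: row {which} has {ungapped} bases but interval spans {len(loc)}"
                )
        for col, (x, y) in enumerate(zip(self.text_a, self.text_b)):
            if x == "-" and y == "-":
                raise ValueError(f"pair {self.id!r}: column {col} is a gap in both rows")

    def __len__(self) -> int:
        return len(self.text_a)

    def row(self, which: str) -> str:
        return self.text_a if which == "a" else self.text_b

    def loc(self, which: str) -> GenomicInterval:
        return self.loc_a if which == "a" else self.loc_b

    def ungapped(self, which: str) -> str:
        return self.row(which).replace("-", "")

    def swapped(self) -> "GappedPair":
        """The same alignment with the two rows exchanged."""
        return GappedPair(self.text_b, self.text_a, self.loc_b, self.loc_a, self.id)


@dataclass
class MultipleAlignment:
    """A small gapped multiple alignment keyed by species label."""

    names: List[str]
    rows: List[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]


# ---------------------------------------------------------------------------
# column <-> genome position maps


def column_to_genome(pair: GappedPair, column: int, which: str) -> Union[int, str]:
    """Genome position of an alignment column in row ``which``, or ``"gap"``.

    Positions count forward from ``loc.start`` along the stored (+-normalized)
    text, so ``genome_to_column(pair, column_to_genome(...))`` is the identity
    on non-gap columns.
    """
    text = pair.row(which)
    if not 0 <= column < len(text):
        raise IndexError(f"column {column} out of range 0..{len(text) - 1}")
    if text[column] == "-":
        return "gap"
    offset = column - text.count("-", 0, column)
    return pair.loc(which).start + offset


def genome_to_column(pair: GappedPair, position: int, which: str) -> int:
    """Alignment column holding genome ``position`` of row ``which``."""
    loc = pair.loc(which)
    if not loc.start <= position < loc.end:
        raise IndexError(f"position {position} outside {loc.start}..{loc.end - 1}")
    target = position - loc.start
    seen = -1
    for col, ch in enumerate(pair.row(which)):
        if ch != "-":
            seen += 1
            if seen == target:
                return col
    raise AssertionError("unreachable: interval length matched ungapped text")


def column_position_index(pair: GappedPair, which: str) -> List[int]:
    """Per-column genome positions for one row; -1 at gap columns."""
    out = []
    pos = pair.loc(which).start
    for ch in pair.row(which):
        if ch == "-":
            out.append(-1)
        else:
            out.append(pos)
            pos += 1
    return out


# ---------------------------------------------------------------------------
# AXT

def read_axt(stream: TextIO) -> Iterator[GappedPair]:
    """Read UCSC AXT blocks as :class:`GappedPair` records.

    AXT coordinates are 1-based inclusive and converted to 0-based half-open.
    Reverse-strand target blocks keep their AXT (reverse-strand-relative)
    coordinates, with ``strand='-'`` recorded on ``loc_b``.
    """
    lines = (ln.rstrip("\n") for ln in stream)
    block_idx = -1
    for line in lines:
        if not line or line.startswith("#"):
            continue
        block_idx += 1
        parts = line.split()
        if len(parts) != 9:
            raise ParseError(f"AXT block {block_idx}: expected 9 header fields, got {len(parts)}")
        (_num, chrom_a, start_a, end_a, chrom_b, start_b, end_b, strand, _score) = parts
        try:
            seq_a = next(lines).strip().upper()
            seq_b = next(lines).strip().upper()
        except StopIteration:
            raise ParseError(f"AXT block {block_idx}: truncated block") from None
        loc_a = GenomicInterval(chrom_a, int(start_a) - 1, int(end_a), "+")
        loc_b = GenomicInterval(chrom_b, int(start_b) - 1, int(end_b), strand)
        if len(seq_a) != len(seq_b):
            raise ParseError(f"AXT block {block_idx}: sequence lengths differ")
        try:
            yield GappedPair(seq_a, seq_b, loc_a, loc_b, id=f"axt{block_idx}")
        except ValueError as exc:
            raise ParseError(f"AXT block {block_idx}: {exc}") from None


def write_axt(pairs: Iterable[GappedPair], stream: TextIO) -> None:
    for i, pair in enumerate(pairs):
        stream.write(
            f"{i} {pair.loc_a.chrom} {pair.loc_a.start + 1} {pair.loc_a.end} "
            f"{pair.loc_b.chrom} {pair.loc_b.start + 1} {pair.loc_b.end} "
            f"{pair.loc_b.strand} 0\n{pair.text_a}\n{pair.text_b}\n\n"
        )


# ---------------------------------------------------------------------------
# MAF

def read_maf(stream: TextIO) -> Iterator[Union[GappedPair, MultipleAlignment]]:
    """Read MAF blocks: 2-species blocks become :class:`GappedPair`, larger
    blocks become :class:`MultipleAlignment`.

    Reverse-strand rows are kept in the given orientation; their interval is
    re-expressed on the + strand using the recorded source size, with
    ``strand='-'``.
    """
    for i, msa in enumerate(AlignIO.parse(stream, "maf")):
        rows = []
        for rec in msa:
            ann = rec.annotations
            start, size, strand, src_size = (
                int(ann["start"]),
                int(ann["size"]),
                ann["strand"],
                int(ann["srcSize"]),
            )
            strand = "+" if strand in (1, "+") else "-"
            if strand == "+":
                loc = GenomicInterval(rec.id, start, start + size, "+")
            else:
                loc = GenomicInterval(rec.id, src_size - start - size, src_size - start, "-")
            rows.append((rec.id, str(rec.seq).upper(), loc))
        if len(rows) < 2:
            raise ParseError(f"MAF block {i}: fewer than 2 rows")
        if len(rows) == 2:
            (ida, ta, la), (idb, tb, lb) = rows
            yield GappedPair(ta, tb, la, lb, id=f"maf{i}")
        else:
            yield MultipleAlignment([r[0] for r in rows], [r[1] for r in rows])


# ---------------------------------------------------------------------------
# aligned pair FASTA

def read_pair_fasta(stream: TextIO) -> GappedPair:
    """Read exactly two equal-length gapped FASTA records as a GappedPair.

    Synthetic coordinates: chrom = record id, start 0. Lowercase is uppercased.
    """
    records = list(SeqIO.parse(stream, "fasta"))
    if len(records) != 2:
        raise ParseError(f"expected exactly 2 FASTA records, got {len(records)}")
    ta, tb = (str(r.seq).upper() for r in records)
    if len(ta) != len(tb):
        raise ParseError("FASTA records have unequal gapped lengths")
    bad = (set(ta) | set(tb)) - _VALID_CHARS
    if bad:
        raise ParseError(f"invalid characters in FASTA records: {sorted(bad)}")
    loc_a = GenomicInterval(records[0].id, 0, len(ta) - ta.count("-"), "+")
    loc_b = GenomicInterval(records[1].id, 0, len(tb) - tb.count("-"), "+")
    return GappedPair(ta, tb, loc_a, loc_b, id=f"{records[0].id}|{records[1].id}")


def write_pair_fasta(pair: GappedPair, stream: TextIO) -> None:
    stream.write(f">{pair.loc_a.chrom}\n{pair.text_a}\n>{pair.loc_b.chrom}\n{pair.text_b}\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(stream: TextIO, sort: bool = False) -> List[GenomicInterval]:
    """Read BED3+ as 0-based half-open intervals (strand from column 6 if present)."""
    out = []
    for i, line in enumerate(stream):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"BED line {i}: fewer than 3 columns")
        start, end = int(parts[1]), int(parts[2])
        if start > end:
            raise ParseError(f"BED line {i}: start > end")
        strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
        out.append(GenomicInterval(parts[0], start, end, strand))
    if sort:
        out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(intervals: Iterable[GenomicInterval], stream: TextIO) -> None:
    for iv in intervals:
        stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# inversion report TSV

TSV_COLUMNS = [
    "id",
    "chromA",
    "startA",
    "endA",
    "chromB",
    "startB",
    "endB",
    "length_bp",
    "criterion",
    "similarity_inverted",
    "similarity_forward",
    "at_exclusive",
    "lineage",
]


def write_inversion_tsv(calls: Sequence, stream: TextIO) -> None:
    """Write finalized inversion calls as a fixed-column TSV, sorted by
    (chromA, startA).  ``calls`` are :class:`umiscan.invsearch.InversionCall`."""
    records = []
    for c in calls:
        records.append(
            {
                "id": c.id,
                "chromA": c.interval_a.chrom,
                "startA": c.interval_a.start,
                "endA": c.interval_a.end,
                "chromB": c.interval_b.chrom,
                "startB": c.interval_b.start,
                "endB": c.interval_b.end,
                "length_bp": c.length_bp,
                "criterion": c.criterion,
                "similarity_inverted": round(c.similarity_inverted, 6),
                "similarity_forward": round(c.similarity_forward, 6),
                "at_exclusive": int(c.at_exclusive),
                "lineage": c.lineage if c.lineage is not None else "NA",
            }
        )
    df = pd.DataFrame.from_records(records, columns=TSV_COLUMNS)
    df = df.sort_values(["chromA", "startA"], kind="stable")
    df.to_csv(stream, sep="\t", index=False)


def read_inversion_tsv(stream: TextIO) -> pd.DataFrame:
    return pd.read_csv(stream, sep="\t", dtype={"criterion": str, "lineage": str})
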