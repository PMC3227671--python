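"""Lineage assignment of inversions by outgroup phylogenetic profiling.

Given a multiple alignment of the human and chimpanzee sequences around an
inversion together with gorilla and/or orangutan outgroups, the species whose
sequence carries the inverted state is identified by counting differences
(mismatch columns plus gap blocks) between each ingroup row and the outgroup
within the inversion's alignment columns: the ingroup that is far from the
outgroup (>= 3 differences) while the other ingroup is close (<= 1) is the one
that inverted.  A count of exactly 2 on either side is deliberately
inconclusive.  When both outgroups are present, gorilla decides the grouping
and orangutan polarizes the ancestral state, which is what exposes incomplete
lineage sorting (gene trees ((human, gorilla), chimpanzee) or
(human, (chimpanzee, gorilla))).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from umiscan.alignio import GappedPair, GenomicInterval, MultipleAlignment
from umiscan.invsearch import InversionCall
from umiscan.pairalign import AlignScoring, DEFAULT_SCORING, star_multi_align

HUMAN = "human"
CHIMPANZEE = "chimpanzee"
GORILLA = "gorilla"
ORANGUTAN = "orangutan"

LINEAGES = (
    "human",
    "chimpanzee",
    "human_gorilla",
    "chimpanzee_gorilla",
    "unresolved",
    "no_outgroup",
)

CLOSE_MAX = 1  # "fewer than two mismatches or gaps"
FAR_MIN = 3  # "three or more mismatches or gaps"


@dataclass(frozen=True)
class LineageCall:
    value: str

    def __post_init__(self) -> None:
        if self.value not in LINEAGES:
            raise ValueError(f"unknown lineage {self.value!r}")


def count_pairwise_diffs(
    msa: MultipleAlignment, row_i: int, row_j: int, col_start: int, col_end: int
) -> int:
    """Mismatch columns plus maximal gap blocks (in either row) between two
    rows of a multiple alignment, within a half-open column window.

    Columns gapped in both rows are skipped; 'N' never matches.  A gap block
    truncated by the window edge still counts once.
    """
    if not (0 <= col_start <= col_end <= msa.column_count):
        raise IndexError("column window out of range")
    a = msa.rows[row_i]
    b = msa.rows[row_j]
    diffs = 0
    col = col_start
    while col < col_end:
        x, y = a[col], b[col]
        if x == "-" and y == "-":
            col += 1
        elif x == "-" or y == "-":
            row = a if x == "-" else b
            other = b if x == "-" else a
            j = col
            while j < col_end and row[j] == "-" and other[j] != "-":
                j += 1
            diffs += 1
            col = j
        else:
            if x != y or x == "N":
                diffs += 1
            col += 1
    return diffs


def _row_index(msa: MultipleAlignment, name: str) -> Optional[int]:
    try:
        return msa.names.index(name)
    except ValueError:
        return None


def assign_lineage(msa: MultipleAlignment, inversion_cols: Tuple[int, int]) -> LineageCall:
    """Assign the inversion in the given column window to a lineage.

    The alignment must contain rows named 'human' and 'chimpanzee' and at
    least one of 'gorilla'/'orangutan'.  Gorilla is the deciding outgroup when
    present; orangutan then polarizes the state to expose incomplete lineage
    sorting.  With orangutan as the only outgroup, ILS categories cannot be
    produced.
    """
    lo, hi = inversion_cols
    ih = _row_index(msa, HUMAN)
    ic = _row_index(msa, CHIMPANZEE)
    if ih is None or ic is None:
        raise ValueError("alignment must contain 'human' and 'chimpanzee' rows")
    ig = _row_index(msa, GORILLA)
    io = _row_index(msa, ORANGUTAN)
    if ig is None and io is None:
        return LineageCall("no_outgroup")

    deciding = ig if ig is not None else io
    d_h = count_pairwise_diffs(msa, ih, deciding, lo, hi)
    d_c = count_pairwise_diffs(msa, ic, deciding, lo, hi)

    if d_h <= CLOSE_MAX and d_c >= FAR_MIN:
        # chimpanzee carries the divergent state
        if ig is not None and io is not None:
            # if orangutan sides with chimpanzee, the human+gorilla state is
            # derived: ILS gene tree ((human, gorilla), chimpanzee)
            d_co = count_pairwise_diffs(msa, ic, io, lo, hi)
            d_ho = count_pairwise_diffs(msa, ih, io, lo, hi)
            if d_co <= CLOSE_MAX and d_ho >= FAR_MIN:
                return LineageCall("human_gorilla")
        return LineageCall("chimpanzee")
    if d_c <= CLOSE_MAX and d_h >= FAR_MIN:
        if ig is not None and io is not None:
            d_ho = count_pairwise_diffs(msa, ih, io, lo, hi)
            d_co = count_pairwise_diffs(msa, ic, io, lo, hi)
            if d_ho <= CLOSE_MAX and d_co >= FAR_MIN:
                return LineageCall("chimpanzee_gorilla")
        return LineageCall("human")
    return LineageCall("unresolved")


# ---------------------------------------------------------------------------


def _extract_row_segment(pair: GappedPair, start: int, end: int, which: str = "a") -> Tuple[str, str]:
    """(row-a substring, row-b substring), ungapped, over the columns where the
    chosen row covers genome positions [start, end)."""
    loc = pair.loc(which)
    start = max(start, loc.start)
    end = min(end, loc.end)
    text = pair.row(which)
    cols = []
    pos = loc.start
    for col, ch in enumerate(text):
        if ch != "-":
            if start <= pos < end:
                cols.append(col)
            pos += 1
    if not cols:
        return "", ""
    lo, hi = cols[0], cols[-1] + 1
    return (
        pair.text_a[lo:hi].replace("-", ""),
        pair.text_b[lo:hi].replace("-", ""),
    )


def profile_callset(
    calls: Sequence[InversionCall],
    pairs: Sequence[GappedPair],
    outgroups: Mapping[str, Sequence[GappedPair]],
    flank: int = 20,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> List[InversionCall]:
    """Annotate each call with its lineage.

    ``pairs`` are the human-chimpanzee alignments the calls came from (row a =
    human).  ``outgroups`` maps 'gorilla'/'orangutan' to alignments whose row a
    is also human.  For each call, outgroup alignments overlapping the human
    inversion interval are gathered (when several overlap, the one covering
    the inversion best is used), the sequences are star-aligned around the
    human row with ``flank`` bp of context, and the lineage rule is applied to
    the inversion's columns.  Calls with no overlapping outgroup are marked
    ``no_outgroup``.  Calls are annotated in place and returned.
    """
    for call in calls:
        iv = call.interval_a
        source = _best_overlap(pairs, iv)
        if source is None:
            call.lineage = "no_outgroup"
            continue
        win_lo, win_hi = iv.start - flank, iv.end + flank
        human_seq, chimp_seq = _extract_row_segment(source, win_lo, win_hi, "a")
        names = [HUMAN, CHIMPANZEE]
        seqs = [human_seq, chimp_seq]
        for species in (GORILLA, ORANGUTAN):
            og_pair = _best_overlap(outgroups.get(species, ()), iv)
            if og_pair is None:
                continue
            _, og_seq = _extract_row_segment(og_pair, win_lo, win_hi, "a")
            if og_seq:
                names.append(species)
                seqs.append(og_seq)
        if len(seqs) < 3 or not human_seq:
            call.lineage = "no_outgroup"
            continue
        msa = star_multi_align(seqs, names, reference_index=0, scoring=scoring)
        cols = _human_window_columns(msa, source, iv, win_lo)
        call.lineage = assign_lineage(msa, cols).value
    return list(calls)


def _best_overlap(
    pairs: Sequence[GappedPair], iv: GenomicInterval
) -> Optional[GappedPair]:
    best, best_ov = None, 0
    for p in pairs:
        loc = p.loc_a
        if loc.chrom != iv.chrom:
            continue
        ov = min(loc.end, iv.end) - max(loc.start, iv.start)
        if ov > best_ov:
            best, best_ov = p, ov
    return best


def _human_window_columns(
    msa: MultipleAlignment, source: GappedPair, iv: GenomicInterval, win_lo: int
) -> Tuple[int, int]:
    """Columns of the star alignment covering the human inversion interval."""
    ref = msa.row(HUMAN)
    offset_lo = max(iv.start - max(win_lo, source.loc_a.start), 0)
    offset_hi = offset_lo + len(iv)
    cols = [c for c, ch in enumerate(ref) if ch != "-"]
    if not cols:
        return 0, 0
    offset_hi = min(offset_hi, len(cols))
    lo = cols[offset_lo] if offset_lo < len(cols) else cols[-1] + 1
    hi = cols[offset_hi - 1] + 1 if offset_hi > offset_lo else lo
    return lo, hi
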