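"""Difference-event enumeration and trio/duo candidate-region extraction.

The null model treats every alignment site independently: a site carries a
difference event (mismatch, or the start of a gap block) with probability
``p_d``, and a gap block with probability ``p_g``.  Three near-adjacent events
("trio") or two gap blocks on opposite rows sandwiching an identical stretch
("duo") are improbable under this null when their span ``n`` satisfies
``P_trio(n) < alpha`` or ``P_duo(n) < alpha``; such windows seed candidate
regions for the inverted-homology search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from umiscan.alignio import GappedPair

DEFAULT_ALPHA = 0.05
DEFAULT_EXTENSION = 50

#: Operating points: per-site densities measured on the human-chimp genome
#: alignments (scan of real data) and the calibrated simulation condition.
HUMAN_CHIMP_RATES = (0.0136, 0.00150)
SIMULATION_RATES = (0.0100, 0.00150)


@dataclass(frozen=True)
class DifferenceEvent:
    """A mismatch column or a maximal gap block.

    ``col_start``/``col_end`` are half-open alignment columns; ``gap_row`` names
    the row carrying the gap ('a'/'b') and is ``None`` for mismatches.
    """

    kind: str  # "mismatch" | "gap_block"
    col_start: int
    col_end: int
    gap_row: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "mismatch":
            if self.col_end - self.col_start != 1 or self.gap_row is not None:
                raise ValueError("mismatch must span one column with gap_row=None")
        elif self.kind == "gap_block":
            if self.gap_row not in ("a", "b"):
                raise ValueError("gap_block requires gap_row 'a' or 'b'")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class RateParams:
    """Per-site difference densities: ``p_d`` counts mismatches + gap blocks,
    ``p_g`` counts gap blocks only."""

    p_d: float
    p_g: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_g <= self.p_d < 1.0):
            raise ValueError(f"require 0 < p_g <= p_d < 1, got p_d={self.p_d}, p_g={self.p_g}")


@dataclass
class CandidateRegion:
    """A merged, extension-padded difference-rich window (half-open columns).

    ``event_spans`` records the (col_start, col_end) spans of the qualifying
    trios/duos that were merged into this region; for duos, ``sandwich`` holds
    the columns strictly between the two gap blocks.
    """

    col_start: int
    col_end: int
    kind: str  # "trio" | "duo"
    span_n: int
    probability: float
    event_spans: List[tuple] = field(default_factory=list)
    sandwich: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.col_start >= self.col_end:
            raise ValueError("empty candidate region")


# ---------------------------------------------------------------------------


def find_difference_events(pair: GappedPair) -> List[DifferenceEvent]:
    """All mismatch columns and maximal gap blocks, sorted by column.

    'N' against anything (including 'N') counts as a mismatch, never a match.
    """
    a, b = pair.text_a, pair.text_b
    events: List[DifferenceEvent] = []
    i, ncol = 0, len(a)
    while i < ncol:
        if a[i] == "-":
            j = i
            while j < ncol and a[j] == "-":
                j += 1
            events.append(DifferenceEvent("gap_block", i, j, "a"))
            i = j
        elif b[i] == "-":
            j = i
            while j < ncol and b[j] == "-":
                j += 1
            events.append(DifferenceEvent("gap_block", i, j, "b"))
            i = j
        else:
            if a[i] != b[i] or a[i] == "N":
                events.append(DifferenceEvent("mismatch", i, i + 1))
            i += 1
    return events


def p_trio(n: int, p_d: float) -> float:
    """Probability that >=2 further difference events fall within the ``n-1``
    sites following a first event:

        P_trio(n) = 1 - (1-p_d)^(n-1) - (n-1) p_d (1-p_d)^(n-2)

    Reduces to ``p_d**2`` at n=3; strictly increasing in both arguments.
    """
    if n < 3:
        raise ValueError("p_trio requires n >= 3")
    if not 0.0 < p_d < 1.0:
        raise ValueError("p_d must be in (0,1)")
    q = 1.0 - p_d
    return 1.0 - q ** (n - 1) - (n - 1) * p_d * q ** (n - 2)


def p_duo(n: int, p_g: float) -> float:
    """Probability that a second gap block falls within the ``n-1`` sites
    following a first one:  P_duo(n) = 1 - (1-p_g)^(n-1).  Reduces to ``p_g``
    at n=2."""
    if n < 2:
        raise ValueError("p_duo requires n >= 2")
    if not 0.0 < p_g < 1.0:
        raise ValueError("p_g must be in (0,1)")
    return 1.0 - (1.0 - p_g) ** (n - 1)


def estimate_rates(pairs: Sequence[GappedPair]) -> RateParams:
    """Empirical (p_d, p_g): event counts over total alignment columns."""
    total_cols = 0
    n_events = 0
    n_gaps = 0
    for pair in pairs:
        total_cols += len(pair)
        for ev in find_difference_events(pair):
            n_events += 1
            if ev.kind == "gap_block":
                n_gaps += 1
    if total_cols == 0:
        raise ValueError("no alignment columns")
    if n_events == 0 or n_gaps == 0:
        raise ValueError(
            "difference-free input: per-site densities of 0 are outside the "
            "model's domain; supply rates explicitly"
        )
    return RateParams(p_d=n_events / total_cols, p_g=n_gaps / total_cols)


# ---------------------------------------------------------------------------


def _qualifying_trio(e1, e2, e3) -> bool:
    """Trio composition rule: 3 mismatches, 2 mismatches + 1 gap block, or
    1 mismatch + 2 gap blocks on *different* rows.  3 gap blocks never qualify."""
    gaps = [e for e in (e1, e2, e3) if e.kind == "gap_block"]
    if len(gaps) == 3:
        return False
    if len(gaps) == 2 and gaps[0].gap_row == gaps[1].gap_row:
        return False
    return True


def find_candidate_regions(
    pair: GappedPair,
    rates: RateParams,
    alpha: float = DEFAULT_ALPHA,
    extension: int = DEFAULT_EXTENSION,
) -> List[CandidateRegion]:
    """Scan the sorted event list for qualifying trios and duos, merge
    overlapping windows, and pad each merged region by ``extension`` columns.

    * Trio: three consecutive events with an admissible composition whose
      column span ``n`` gives ``p_trio(n) < alpha``.
    * Duo: two consecutive gap blocks on different rows (so the columns in
      between are identically aligned by construction) whose span gives
      ``p_duo(n) < alpha``.

    Spans are measured in alignment columns from the first column of the first
    event to the last column of the final event, inclusive.  Trio and duo
    windows are merged separately (they feed different admission criteria);
    merged regions of the same kind never overlap.
    """
    events = find_difference_events(pair)
    ncol = len(pair)
    raw: List[CandidateRegion] = []

    for k in range(len(events) - 2):
        e1, e2, e3 = events[k], events[k + 1], events[k + 2]
        if not _qualifying_trio(e1, e2, e3):
            continue
        n = e3.col_end - e1.col_start
        prob = p_trio(n, rates.p_d)
        if prob < alpha:
            raw.append(
                CandidateRegion(
                    e1.col_start, e3.col_end, "trio", n, prob,
                    event_spans=[(e1.col_start, e3.col_end)],
                )
            )

    for k in range(len(events) - 1):
        e1, e2 = events[k], events[k + 1]
        if e1.kind != "gap_block" or e2.kind != "gap_block":
            continue
        if e1.gap_row == e2.gap_row:
            continue
        n = e2.col_end - e1.col_start
        prob = p_duo(n, rates.p_g)
        if prob < alpha:
            raw.append(
                CandidateRegion(
                    e1.col_start, e2.col_end, "duo", n, prob,
                    event_spans=[(e1.col_start, e2.col_end)],
                    sandwich=(e1.col_end, e2.col_start),
                )
            )

    out: List[CandidateRegion] = []
    for kind in ("trio", "duo"):
        group = sorted((r for r in raw if r.kind == kind), key=lambda r: r.col_start)
        merged: List[CandidateRegion] = []
        for r in group:
            if merged and r.col_start < merged[-1].col_end:
                last = merged[-1]
                last.col_end = max(last.col_end, r.col_end)
                last.span_n = last.col_end - last.col_start
                last.probability = min(last.probability, r.probability)
                last.event_spans.extend(r.event_spans)
            else:
                merged.append(r)
        for r in merged:
            r.col_start = max(0, r.col_start - extension)
            r.col_end = min(ncol, r.col_end + extension)
            out.append(r)
    out.sort(key=lambda r: (r.col_start, r.col_end, r.kind))
    return out
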