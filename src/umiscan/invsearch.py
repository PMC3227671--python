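"""Inverted-homology search and inversion-call classification.

Within each difference-rich candidate region, the reverse complement of one
species' segment is searched against the other species' segment with a
blastn-like strategy: exact ``word_size``-mer seeding, optimal local affine-gap
alignment, and a Karlin-Altschul E-value reporting threshold.  Hits are then
admitted as ultramicro inversions under two criteria:

* criterion (i), for trio-seeded regions: the inverted alignment lies (almost)
  entirely within the forwardly aligned region, its similarity exceeds
  ``min_inverted_similarity`` and exceeds ``similarity_ratio`` times the
  similarity of the corresponding forward sub-alignment, and that forward
  sub-alignment contains the trio of difference events;
* criterion (ii), for duo-seeded regions (partially palindromic inversions):
  the inverted alignment is perfect, covers the entire gap-sandwiched
  identically aligned stretch, and that stretch makes up more than
  ``duo_identity_fraction`` of the inverted segment.

Finally, AT-exclusive calls explainable as stretch/shrink of A/T mononucleotide
runs or phase-shifted AT dinucleotide repeats are filtered out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from umiscan.alignio import GappedPair, GenomicInterval, column_position_index
from umiscan.diffscan import (
    CandidateRegion,
    RateParams,
    find_candidate_regions,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(s: str) -> str:
    """Reverse complement over the A,C,G,T,N alphabet (an involution)."""
    bad = set(s.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return s.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds of the inversion detector.

    The local-aligner scores mirror legacy blastn defaults (+1/-3, gap open 5,
    gap extend 2); ``expect`` is the E-value reporting threshold with
    Karlin-Altschul parameters ``ka_lambda``/``ka_k`` appropriate for that
    scoring, computed over the raw search space m*n of the two segments.

    ``gap_decay`` reproduces the significance convention of the legacy NCBI
    blastall program, which divided a single HSP's E-value by
    ``1 - gap_decay_rate`` (0.5) before comparing it with the expect cutoff;
    near the short-hit reporting boundary this raises the minimum reportable
    raw score by about one, which is what makes marginal 5-6 bp inverted hits
    scarce.  Modern blastn+ omits the divisor; set ``gap_decay = 0`` for
    blastn+-equivalent reporting.
    """

    word_size: int = 5
    min_inverted_similarity: float = 0.95
    similarity_ratio: float = 1.25
    min_overlap_fraction: float = 0.80
    duo_identity_fraction: float = 0.50
    max_inversion_length: int = 125
    min_inversion_length: int = 5
    match: int = 1
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    expect: float = 10.0
    ka_lambda: float = 1.374
    ka_k: float = 0.711
    gap_decay: float = 0.5
    #: raw-score threshold an ungapped core must reach before a gapped
    #: alignment is reported (blastn's "gap trigger", ~22 bits for these
    #: Karlin-Altschul parameters); purely ungapped hits are exempt
    gap_trigger: int = 11
    max_hits: int = 32

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        for name in ("min_inverted_similarity", "min_overlap_fraction", "duo_identity_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")

    def min_reportable_score(self, m: int, n: int) -> int:
        """Smallest raw score whose (gap-decay-weighted) E-value
        K*m*n*exp(-lambda*S) / (1 - gap_decay) is <= expect."""
        if m <= 0 or n <= 0:
            return 1
        effective = self.expect * (1.0 - self.gap_decay)
        s = math.log(self.ka_k * m * n / effective) / self.ka_lambda
        return max(1, math.ceil(s - 1e-9))


DEFAULT_DETECTOR = DetectorConfig()


@dataclass
class LocalHit:
    """One local alignment between segment A (forward) and segment B
    (reverse-complement orientation).

    ``a_*`` are ungapped positions within segment A; ``b_*`` are ungapped
    positions within the reverse-complemented segment B (so position 0 is the
    last base of the original segment)."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str
    score: int
    similarity: float


@dataclass
class InversionCall:
    """A detected ultramicro inversion with both-genome coordinates."""

    interval_a: GenomicInterval
    interval_b: GenomicInterval
    length_bp: int
    criterion: str  # "i" | "ii"
    similarity_inverted: float
    similarity_forward: float
    at_exclusive: bool
    source_region: CandidateRegion
    segment_a: str
    segment_b: str
    lineage: Optional[str] = None
    id: str = ""


# ---------------------------------------------------------------------------
# similarity


def similarity(aligned_a: str, aligned_b: str) -> float:
    """Identical columns / total columns; gap columns count as non-identical,
    and 'N' never matches."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings have unequal lengths")
    if not aligned_a:
        raise ValueError("empty alignment")
    ident = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x == y and x not in ("-", "N")
    )
    return ident / len(aligned_a)


# ---------------------------------------------------------------------------
# seed-and-extend search


def _kmers(s: str, k: int) -> set:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def _make_local_aligner(cfg: DetectorConfig) -> Align.PairwiseAligner:
    alpha = "ACGTNX"
    m = np.full((6, 6), float(cfg.mismatch))
    for i in range(4):
        m[i, i] = float(cfg.match)
    m[4, :] = float(cfg.mismatch)  # N never matches, not even N-N
    m[:, 4] = float(cfg.mismatch)
    m[5, :] = -1e6  # X masks previously reported hit positions
    m[:, 5] = -1e6
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.Array(alpha, dims=2, data=m)
    aligner.open_gap_score = -(cfg.gap_open + cfg.gap_extend)
    aligner.extend_gap_score = -cfg.gap_extend
    return aligner


def _max_ungapped_core_score(aligned_a: str, aligned_b: str, cfg: DetectorConfig) -> int:
    """Best raw score of any gap-free stretch of the alignment (the ungapped
    HSP a seeded search would have extended before attempting gaps)."""
    best = 0
    run = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            run = 0
            continue
        s = cfg.match if (x == y and x != "N") else cfg.mismatch
        run = max(run + s, 0)
        best = max(best, run)
    return best


def _has_seed_run(aligned_a: str, aligned_b: str, k: int) -> bool:
    """True iff the alignment contains >= k consecutive identity columns
    (no gaps) — the exact word a seeded search needs to find the hit."""
    run = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == y and x != "-" and x != "N":
            run += 1
            if run >= k:
                return True
        else:
            run = 0
    return False


def _pick_consistent(alignments, query_len: int, cap: int = 24):
    """Among co-optimal local alignments, prefer the one pairing homologous
    positions.

    The search's contract is that the query is the reverse complement of the
    target's counterpart segment, so for a genuine inversion the target span
    [a_start, a_end) and the un-reversed query span [nq - b_end, nq - b_start)
    nearly coincide.  Score-tied hits elsewhere in the segment (chance repeats
    of the same word) are deprioritized by distance between those spans.
    """
    best = None
    best_key = None
    top_score = None
    for i, aln in enumerate(alignments):
        if i >= cap:
            break
        if top_score is None:
            top_score = aln.score
        elif aln.score < top_score:
            break
        blocks = aln.aligned
        a_start, a_end = int(blocks[0][0][0]), int(blocks[0][-1][1])
        b_start, b_end = int(blocks[1][0][0]), int(blocks[1][-1][1])
        shift = abs(a_start - (query_len - b_end)) + abs(a_end - (query_len - b_start))
        key = (shift, a_start, b_start)
        if best_key is None or key < best_key:
            best, best_key = aln, key
    return best


def _seeded_diagonals(query: str, target: str, k: int) -> set:
    """Diagonals (a_pos - b_pos) carrying at least one exact k-mer match."""
    by_word = {}
    for i in range(len(query) - k + 1):
        by_word.setdefault(query[i:i + k], []).append(i)
    diags = set()
    for j in range(len(target) - k + 1):
        for i in by_word.get(target[j:j + k], ()):
            diags.add(j - i)
    return diags


def _ungapped_diagonal_hits(
    query: str, target: str, cfg: DetectorConfig, min_score: int
) -> List[LocalHit]:
    """Maximal-scoring ungapped segments along every seeded diagonal.

    This mirrors blastn's per-seed ungapped extension: every seeded diagonal is
    walked once and each positive-scoring stretch contributes its best
    segment, so strong hits never shadow weaker ones elsewhere in the region
    (unlike a global best-hit search).
    """
    hits: List[LocalHit] = []
    for d in _seeded_diagonals(query, target, cfg.word_size):
        b0 = max(0, -d)
        a0 = b0 + d
        length = min(len(target) - a0, len(query) - b0)
        if length < cfg.word_size:
            continue
        run_score = 0
        run_start = 0
        best = 0
        best_span = None
        pos = 0
        while pos <= length:
            end_of_run = pos == length
            if not end_of_run:
                x = target[a0 + pos]
                y = query[b0 + pos]
                s = cfg.match if (x == y and x != "N") else cfg.mismatch
                run_score += s
            if end_of_run or run_score <= 0:
                if best_span is not None and best >= min_score:
                    lo, hi = best_span
                    aligned_a = target[a0 + lo:a0 + hi]
                    aligned_b = query[b0 + lo:b0 + hi]
                    if _has_seed_run(aligned_a, aligned_b, cfg.word_size):
                        hits.append(
                            LocalHit(
                                a0 + lo, a0 + hi, b0 + lo, b0 + hi,
                                aligned_a, aligned_b, best,
                                similarity(aligned_a, aligned_b),
                            )
                        )
                run_score = 0
                run_start = pos + 1
                best = 0
                best_span = None
            elif run_score > best:
                # positive stretches start on a match and prefixes have
                # positive score, so [run_start, argmax] is the stretch's
                # maximal segment
                best = run_score
                best_span = (run_start, pos + 1)
            pos += 1
    return hits


def seed_extend_search(query: str, target: str, cfg: DetectorConfig = DEFAULT_DETECTOR) -> List[LocalHit]:
    """Local alignments of ``query`` (reverse-complemented segment B) against
    ``target`` (segment A), blastn-style.

    A hit exists only if the two strings share an exact ``word_size``-mer; each
    reported alignment must itself contain a ``word_size`` identity run and a
    raw score meeting the E-value threshold.  Two complementary enumeration
    routes are merged: exact maximal ungapped segments along every seeded
    diagonal, and optimal gapped local alignments found best-first with
    iterative masking of the target.  Hits are returned sorted by score
    descending, ties broken by (a_start, b_start).
    """
    query, target = query.upper(), target.upper()
    k = cfg.word_size
    if len(query) < k or len(target) < k:
        return []
    if not (_kmers(query, k) & _kmers(target, k)):
        return []
    min_score = cfg.min_reportable_score(len(query), len(target))
    aligner = _make_local_aligner(cfg)
    nq = len(query)
    hits: List[LocalHit] = list(_ungapped_diagonal_hits(query, target, cfg, min_score))
    seen = {(h.a_start, h.a_end, h.b_start, h.b_end) for h in hits}
    masked = target
    for _ in range(cfg.max_hits):
        try:
            alns = aligner.align(masked, query)
            aln = _pick_consistent(alns, nq)
        except (ValueError, OverflowError, IndexError):
            break
        if aln is None:
            break
        score = int(round(aln.score))
        if score < min_score:
            break
        blocks = aln.aligned
        a_start, a_end = int(blocks[0][0][0]), int(blocks[0][-1][1])
        b_start, b_end = int(blocks[1][0][0]), int(blocks[1][-1][1])
        aligned_a, aligned_b = str(aln[0]), str(aln[1])
        key = (a_start, a_end, b_start, b_end)
        gapped = "-" in aligned_a or "-" in aligned_b
        if gapped and _max_ungapped_core_score(aligned_a, aligned_b, cfg) < cfg.gap_trigger:
            # a seeded search never attempts gapped extension from such a
            # weak ungapped core; mask and move on
            masked = masked[:a_start] + "X" * (a_end - a_start) + masked[a_end:]
            continue
        if key not in seen and _has_seed_run(aligned_a, aligned_b, k):
            seen.add(key)
            hits.append(
                LocalHit(
                    a_start,
                    a_end,
                    b_start,
                    b_end,
                    aligned_a,
                    aligned_b,
                    score,
                    similarity(aligned_a, aligned_b),
                )
            )
        masked = masked[:a_start] + "X" * (a_end - a_start) + masked[a_end:]
    hits.sort(key=lambda h: (-h.score, h.a_start, h.b_start))
    return hits


# ---------------------------------------------------------------------------
# region classification


class _RegionFrame:
    """Coordinate bookkeeping for one candidate region of a GappedPair."""

    def __init__(self, pair: GappedPair, region: CandidateRegion):
        self.pair = pair
        self.region = region
        cs, ce = region.col_start, region.col_end
        self.cols_a: List[int] = []  # column of each ungapped A position in region
        self.cols_b: List[int] = []
        seg_a = []
        seg_b = []
        for col in range(cs, ce):
            if pair.text_a[col] != "-":
                self.cols_a.append(col)
                seg_a.append(pair.text_a[col])
            if pair.text_b[col] != "-":
                self.cols_b.append(col)
                seg_b.append(pair.text_b[col])
        self.seg_a = "".join(seg_a)
        self.seg_b = "".join(seg_b)
        # genome offsets of the first region position in each species
        a_before = sum(1 for col in range(cs) if pair.text_a[col] != "-")
        b_before = sum(1 for col in range(cs) if pair.text_b[col] != "-")
        self.a_genome0 = pair.loc_a.start + a_before
        self.b_genome0 = pair.loc_b.start + b_before

    def usable(self, cfg: DetectorConfig) -> bool:
        """Long enough to seed, and not dominated by ambiguity: regions whose
        segments are more than half 'N' (assembly gaps) are skipped."""
        for seg in (self.seg_a, self.seg_b):
            if len(seg) < cfg.word_size:
                return False
            if seg.count("N") > 0.5 * len(seg):
                return False
        return True

    def hit_columns(self, hit: LocalHit) -> Tuple[int, int]:
        """Half-open column span of the hit's A-side positions."""
        lo = self.cols_a[hit.a_start]
        hi = self.cols_a[hit.a_end - 1] + 1
        return lo, hi

    def hit_columns_b(self, hit: LocalHit) -> Tuple[int, int]:
        """Half-open column span of the hit's B-side positions (original
        orientation)."""
        nb = len(self.seg_b)
        lo = self.cols_b[nb - hit.b_end]
        hi = self.cols_b[nb - hit.b_start - 1] + 1
        return lo, hi

    def two_sided(self, hit: LocalHit) -> bool:
        """The inverted alignment pairs homologous stretches: its A-side and
        B-side column footprints must overlap, otherwise the hit links two
        different parts of the forward alignment (a chance repeat, not an
        inversion in place)."""
        a_lo, a_hi = self.hit_columns(hit)
        b_lo, b_hi = self.hit_columns_b(hit)
        return a_lo < b_hi and b_lo < a_hi

    def forward_similarity(self, col_lo: int, col_hi: int) -> float:
        return similarity(self.pair.text_a[col_lo:col_hi], self.pair.text_b[col_lo:col_hi])

    def forward_aligned_fraction(self, hit: LocalHit) -> float:
        """Fraction of the hit's A positions whose column is forwardly aligned
        (non-gap in both rows); the remainder sit opposite gaps in B."""
        cols = self.cols_a[hit.a_start:hit.a_end]
        aligned = sum(1 for c in cols if self.pair.text_b[c] != "-")
        return aligned / len(cols)

    def hit_intervals(self, hit: LocalHit) -> Tuple[GenomicInterval, GenomicInterval]:
        loc_a, loc_b = self.pair.loc_a, self.pair.loc_b
        ia = GenomicInterval(
            loc_a.chrom, self.a_genome0 + hit.a_start, self.a_genome0 + hit.a_end, loc_a.strand
        )
        # b coordinates: hit.b_* live on the reverse complement of seg_b
        nb = len(self.seg_b)
        b_lo = nb - hit.b_end
        b_hi = nb - hit.b_start
        ib = GenomicInterval(
            loc_b.chrom, self.b_genome0 + b_lo, self.b_genome0 + b_hi, loc_b.strand
        )
        return ia, ib

    def hit_segments(self, hit: LocalHit) -> Tuple[str, str]:
        """Ungapped inverted segments in each species' forward orientation."""
        seg_a = self.seg_a[hit.a_start:hit.a_end]
        nb = len(self.seg_b)
        seg_b = self.seg_b[nb - hit.b_end:nb - hit.b_start]
        return seg_a, seg_b


def _length_ok(hit: LocalHit, cfg: DetectorConfig) -> bool:
    length = hit.a_end - hit.a_start
    return cfg.min_inversion_length <= length <= cfg.max_inversion_length


def _build_call(
    frame: _RegionFrame, hit: LocalHit, criterion: str, sim_fwd: float, cfg: DetectorConfig
) -> InversionCall:
    ia, ib = frame.hit_intervals(hit)
    seg_a, seg_b = frame.hit_segments(hit)
    call = InversionCall(
        interval_a=ia,
        interval_b=ib,
        length_bp=hit.a_end - hit.a_start,
        criterion=criterion,
        similarity_inverted=hit.similarity,
        similarity_forward=sim_fwd,
        at_exclusive=False,
        source_region=frame.region,
        segment_a=seg_a,
        segment_b=seg_b,
    )
    call.at_exclusive = classify_at_exclusive(call)
    return call


def classify_trio_candidate(
    region: CandidateRegion, pair: GappedPair, cfg: DetectorConfig = DEFAULT_DETECTOR
) -> Optional[InversionCall]:
    """Apply criterion (i) to a trio-seeded region; best passing hit wins."""
    if region.kind != "trio":
        raise ValueError("classify_trio_candidate requires a trio region")
    frame = _RegionFrame(pair, region)
    if not frame.usable(cfg):
        return None
    hits = seed_extend_search(reverse_complement(frame.seg_b), frame.seg_a, cfg)
    for hit in hits:
        if not _length_ok(hit, cfg):
            continue
        if not frame.two_sided(hit):
            continue
        # complete inclusion in the forward alignment (fraction 1.0) or >80%
        # overlap with the remainder of the hit sitting opposite gaps
        if frame.forward_aligned_fraction(hit) <= cfg.min_overlap_fraction:
            continue
        if hit.similarity <= cfg.min_inverted_similarity:
            continue
        col_lo, col_hi = frame.hit_columns(hit)
        sim_fwd = frame.forward_similarity(col_lo, col_hi)
        if hit.similarity <= cfg.similarity_ratio * sim_fwd:
            continue
        # the forward alignment corresponding to the hit must include a trio
        if not any(s >= col_lo and e <= col_hi for s, e in region.event_spans):
            continue
        return _build_call(frame, hit, "i", sim_fwd, cfg)
    return None


def classify_duo_candidate(
    region: CandidateRegion, pair: GappedPair, cfg: DetectorConfig = DEFAULT_DETECTOR
) -> Optional[InversionCall]:
    """Apply criterion (ii) — partially palindromic inversions — to a
    duo-seeded region."""
    if region.kind != "duo":
        raise ValueError("classify_duo_candidate requires a duo region")
    frame = _RegionFrame(pair, region)
    if not frame.usable(cfg):
        return None
    # gap-sandwich structures inside the region: consecutive gap blocks on
    # different rows with only identity columns between them
    sandwiches = _duo_sandwiches(pair, region)
    if not sandwiches:
        return None
    hits = seed_extend_search(reverse_complement(frame.seg_b), frame.seg_a, cfg)
    for hit in hits:
        if not _length_ok(hit, cfg):
            continue
        if not frame.two_sided(hit):
            continue
        if hit.similarity < 1.0:
            continue
        col_lo, col_hi = frame.hit_columns(hit)
        for sand_lo, sand_hi, span in sandwiches:
            if sand_hi <= sand_lo:
                continue
            # the inverted region must cover the whole forwardly aligned
            # (sandwiched) stretch ...
            if not (col_lo <= sand_lo and sand_hi <= col_hi):
                continue
            # ... and that identically aligned stretch must exceed half the
            # inverted segment
            seg_len = hit.a_end - hit.a_start
            if (sand_hi - sand_lo) <= cfg.duo_identity_fraction * seg_len:
                continue
            sim_fwd = frame.forward_similarity(col_lo, col_hi)
            return _build_call(frame, hit, "ii", sim_fwd, cfg)
    return None


def _duo_sandwiches(pair: GappedPair, region: CandidateRegion) -> List[Tuple[int, int, Tuple[int, int]]]:
    """(sandwich_lo, sandwich_hi, duo_span) for each gap-block duo recorded in
    the region (column coordinates)."""
    out = []
    from umiscan.diffscan import find_difference_events

    events = [
        e
        for e in find_difference_events(pair)
        if e.col_start >= region.col_start and e.col_end <= region.col_end
    ]
    for e1, e2 in zip(events, events[1:]):
        if (
            e1.kind == "gap_block"
            and e2.kind == "gap_block"
            and e1.gap_row != e2.gap_row
        ):
            out.append((e1.col_end, e2.col_start, (e1.col_start, e2.col_end)))
    return out


# ---------------------------------------------------------------------------
# AT filters


def _is_at_mono(s: str) -> bool:
    """A run of A's followed by a run of T's (either possibly empty)."""
    if not s or set(s) - {"A", "T"}:
        return False
    i = 0
    while i < len(s) and s[i] == "A":
        i += 1
    return all(c == "T" for c in s[i:])


def _is_at_alternating(s: str) -> bool:
    """A phase of an AT dinucleotide repeat (no two adjacent equal bases)."""
    if not s or set(s) - {"A", "T"}:
        return False
    return all(x != y for x, y in zip(s, s[1:]))


def at_repeat_filter(call: InversionCall, pair: Optional[GappedPair] = None) -> bool:
    """True = discard: the segment pair is explainable without an inversion,
    either as stretch/shrink of A/T mononucleotide runs (A^i T^j vs A^k T^m)
    or as phase-shifted AT dinucleotide repeats (ATAT... vs TATA...)."""
    a, b = call.segment_a, call.segment_b
    if _is_at_mono(a) and _is_at_mono(b):
        return True
    if _is_at_alternating(a) and _is_at_alternating(b):
        return True
    return False


def classify_at_exclusive(call: InversionCall, pair: Optional[GappedPair] = None) -> bool:
    """True iff both species' inverted segments contain only A and T."""
    ab = call.segment_a + call.segment_b
    return bool(ab) and not (set(ab) - {"A", "T"})


# ---------------------------------------------------------------------------
# end-to-end scan


def scan_pair(
    pair: GappedPair,
    rates: RateParams,
    cfg: DetectorConfig = DEFAULT_DETECTOR,
    alpha: float = 0.05,
    extension: int = 50,
) -> List[InversionCall]:
    """Scan one pairwise alignment end-to-end: difference events, trio/duo
    candidate regions, inverted-homology classification, overlap
    deduplication, AT filters.  Deterministic given its inputs."""
    regions = find_candidate_regions(pair, rates, alpha=alpha, extension=extension)
    calls: List[InversionCall] = []
    for region in regions:
        if region.kind == "trio":
            call = classify_trio_candidate(region, pair, cfg)
        else:
            call = classify_duo_candidate(region, pair, cfg)
        if call is not None:
            calls.append(call)
    # merge overlapping trio/duo calls: keep the higher-similarity one
    calls.sort(key=lambda c: (c.interval_a.start, c.interval_a.end))
    deduped: List[InversionCall] = []
    for call in calls:
        if deduped and call.interval_a.overlaps(deduped[-1].interval_a):
            prev = deduped[-1]
            key = lambda c: (c.similarity_inverted, -c.interval_a.start)
            if key(call) > key(prev):
                deduped[-1] = call
        else:
            deduped.append(call)
    kept = [c for c in deduped if not at_repeat_filter(c, pair)]
    for i, call in enumerate(kept):
        call.id = f"{pair.id}:inv{i}" if pair.id else f"inv{i}"
    return kept
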