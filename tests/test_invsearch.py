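"""Inverted-homology search, admission criteria, and AT filters."""

import pytest
from hypothesis import given, settings, strategies as st

import numpy as np

from umiscan.diffscan import RateParams, find_candidate_regions
from umiscan.invsearch import (
    DetectorConfig,
    at_repeat_filter,
    classify_at_exclusive,
    classify_duo_candidate,
    classify_trio_candidate,
    reverse_complement,
    scan_pair,
    seed_extend_search,
    similarity,
)
from umiscan.pairalign import global_affine_align

from conftest import make_pair

RATES = RateParams(0.0100, 0.0015)
CFG = DetectorConfig()

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestReverseComplement:
    def test_palindrome(self):
        assert reverse_complement("ACGT") == "ACGT"

    def test_simple(self):
        assert reverse_complement("AAAT") == "ATTT"

    @given(dna)
    @settings(max_examples=100, derandomize=True)
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")


class TestSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 1.0), ("ACGT", "ACGA", 0.75), ("AC-T", "ACGT", 0.75)],
    )
    def test_examples(self, a, b, expected):
        assert similarity(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            similarity("ACGT", "ACG")


def oracle_local_score(q: str, t: str, cfg: DetectorConfig) -> int:
    """Exhaustive Smith-Waterman with affine gaps, written independently
    (three explicit DP matrices, no vectorization)."""
    nq, nt = len(q), len(t)
    NEG = -10**9
    H = [[0] * (nq + 1) for _ in range(nt + 1)]
    E = [[NEG] * (nq + 1) for _ in range(nt + 1)]  # gap in query
    F = [[NEG] * (nq + 1) for _ in range(nt + 1)]  # gap in target
    best = 0
    for i in range(1, nt + 1):
        for j in range(1, nq + 1):
            E[i][j] = max(H[i - 1][j] - cfg.gap_open - cfg.gap_extend, E[i - 1][j] - cfg.gap_extend)
            F[i][j] = max(H[i][j - 1] - cfg.gap_open - cfg.gap_extend, F[i][j - 1] - cfg.gap_extend)
            sub = cfg.match if t[i - 1] == q[j - 1] else cfg.mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSeedExtendSearch:
    def test_identical_segments_full_length_hit(self):
        s = "ACGTTGCAACGTTGCAACGT"
        hits = seed_extend_search(s, s, CFG)
        assert hits and hits[0].a_start == 0 and hits[0].a_end == len(s)
        assert hits[0].similarity == 1.0

    def test_no_shared_word_no_hits(self):
        assert seed_extend_search("AAAAAAAAAA", "CCCCCCCCCC", CFG) == []

    def test_top_hit_matches_exhaustive_local_alignment(self, rng):
        bases = list("ACGT")
        checked = 0
        for _ in range(60):
            core = "".join(rng.choice(bases, size=8))
            q = "".join(rng.choice(bases, size=10)) + core + "".join(rng.choice(bases, size=8))
            t = "".join(rng.choice(bases, size=6)) + core + "".join(rng.choice(bases, size=12))
            q, t = q[:30], t[:30]
            hits = seed_extend_search(q, t, CFG)
            assert hits, "planted 8-mer guarantees a seed"
            assert hits[0].score == oracle_local_score(q, t, CFG)
            checked += 1
        assert checked == 60

    def test_random_pairs_never_beat_oracle(self, rng):
        bases = list("ACGT")
        for _ in range(40):
            q = "".join(rng.choice(bases, size=25))
            t = "".join(rng.choice(bases, size=25))
            hits = seed_extend_search(q, t, CFG)
            if hits:
                assert hits[0].score <= oracle_local_score(q, t, CFG)

    def test_min_reportable_score_scales_with_search_space(self):
        assert CFG.min_reportable_score(105, 105) >= CFG.min_reportable_score(20, 20)
        modern = DetectorConfig(gap_decay=0.0)
        assert modern.min_reportable_score(105, 105) <= CFG.min_reportable_score(105, 105)


def plant_inversion_pair(rng, flank=120, length=10, palindrome=False):
    """Identical flanks with a reverse-complemented middle segment."""
    bases = list("ACGT")
    while True:
        if palindrome:
            half = "".join(rng.choice(bases, size=length // 2))
            seg = half + reverse_complement(half)
        else:
            seg = "".join(rng.choice(bases, size=length))
            if seg == reverse_complement(seg):
                continue
        left = "".join(rng.choice(bases, size=flank))
        right = "".join(rng.choice(bases, size=flank))
        a = left + seg + right
        b = left + reverse_complement(seg) + right
        # demand a difference-dense signature so the fixture is a guaranteed trio
        diffs = sum(x != y for x, y in zip(a, b))
        if palindrome or diffs >= 3:
            return a, b, (flank, flank + length)


class TestTrioClassification:
    def test_planted_inversion_called_and_explains_region(self, rng):
        for _ in range(10):
            a, b, (lo, hi) = plant_inversion_pair(rng, length=10)
            pair = global_affine_align(a, b)
            calls = scan_pair(pair, RATES, CFG)
            matching = [
                c for c in calls
                if c.interval_b.start < hi and lo < c.interval_b.end
            ]
            assert matching, "planted 10 bp inversion must be recovered"
            call = matching[0]
            assert call.criterion == "i"
            assert call.similarity_inverted > 0.95
            # the call explains the region: undoing the inversion restores identity
            s, e = call.interval_b.start, call.interval_b.end
            restored = b[:s] + reverse_complement(b[s:e]) + b[e:]
            before = similarity(a, b)
            after = similarity(a, restored)
            assert after > before

    def test_perfect_palindrome_invisible(self, rng):
        a, b, _ = plant_inversion_pair(rng, length=10, palindrome=True)
        assert a == b  # palindrome inverts to itself: no signature at all
        pair = global_affine_align(a, b)
        assert scan_pair(pair, RATES, CFG) == []

    def test_similarity_ratio_threshold_arithmetic(self):
        # inverted 0.96 vs forward 0.90: 0.96 < 1.25 * 0.90, must be rejected
        cfg = CFG
        assert not (0.96 > cfg.similarity_ratio * 0.90)
        assert 0.96 > cfg.similarity_ratio * 0.75


class TestDuoClassification:
    def test_partially_palindromic_inversion_criterion_ii(self, rng):
        # segment = short non-palindromic prefix + self-reverse-complementary
        # core: after inversion the core still aligns forwardly and the prefix
        # re-appears reverse-complemented on the other side, leaving two gap
        # blocks on different rows around an identical sandwich
        bases = list("ACGT")
        found = 0
        for _ in range(30):
            half = "".join(rng.choice(bases, size=4))
            core = half + reverse_complement(half)
            prefix = "".join(rng.choice(bases, size=3))
            seg = prefix + core
            left = "".join(rng.choice(bases, size=100))
            right = "".join(rng.choice(bases, size=100))
            a = left + seg + right
            b = left + reverse_complement(seg) + right  # == left + core + rc(prefix) + right
            pair = global_affine_align(a, b)
            calls = scan_pair(pair, RATES, CFG)
            found += any(c.criterion == "ii" for c in calls)
        assert found >= 15, "partially palindromic inversions should mostly be called via the duo route"

    def test_duo_requires_perfect_inverted_similarity(self, rng):
        # any mismatch inside the inverted alignment disqualifies criterion (ii)
        for region_pair in range(5):
            a, b, (lo, hi) = plant_inversion_pair(rng, length=12)
            pair = global_affine_align(a, b)
            for region in find_candidate_regions(pair, RATES):
                if region.kind != "duo":
                    continue
                call = classify_duo_candidate(region, pair, CFG)
                if call is not None:
                    assert call.similarity_inverted == 1.0


class TestAtFilters:
    def test_mononucleotide_stretch_pattern_discarded(self):
        # printed exemplar: inverting AAATTTTTTT yields AAAAAAATTT, which
        # stretch/shrink of the A and T runs also explains
        call = _fake_call("AAATTTTTTT", "AAAAAAATTT")
        assert at_repeat_filter(call) is True

    def test_staggered_dinucleotide_pattern_discarded(self):
        call = _fake_call("ATATATATATA", "TATATATATAT")
        assert at_repeat_filter(call) is True

    def test_non_repeat_at_segment_kept(self):
        call = _fake_call("AATTTAT", "ATAAATT")
        assert at_repeat_filter(call) is False

    def test_at_exclusive_classification(self, rng):
        assert classify_at_exclusive(_fake_call("ATTA", "TAAT")) is True
        assert classify_at_exclusive(_fake_call("ATGA", "TCAT")) is False
        for _ in range(20):
            s = "".join(rng.choice(list("AT"), size=rng.integers(5, 30)))
            assert classify_at_exclusive(_fake_call(s, reverse_complement(s))) is True

    def test_scanned_calls_never_match_filter_patterns(self, rng):
        # property: no emitted call's segments form the mono/di-nucleotide patterns
        for _ in range(5):
            a, b, _ = plant_inversion_pair(rng, length=8)
            pair = global_affine_align(a, b)
            for call in scan_pair(pair, RATES, CFG):
                assert not at_repeat_filter(call)


def _fake_call(seg_a, seg_b):
    from umiscan.alignio import GenomicInterval
    from umiscan.invsearch import InversionCall

    return InversionCall(
        interval_a=GenomicInterval("a", 0, len(seg_a)),
        interval_b=GenomicInterval("b", 0, len(seg_b)),
        length_bp=len(seg_a),
        criterion="i",
        similarity_inverted=1.0,
        similarity_forward=0.0,
        at_exclusive=False,
        source_region=None,
        segment_a=seg_a,
        segment_b=seg_b,
    )


class TestScanPair:
    def test_n_dense_regions_skipped(self):
        # a difference-dense patch made of N against bases must not be searched
        text_a = "ACGT" * 15 + "N" * 12 + "ACGT" * 15
        text_b = "ACGT" * 15 + "TGCATGCATGCA" + "ACGT" * 15
        pair = make_pair(text_a, text_b)
        assert scan_pair(pair, RATES, CFG) == []

    def test_identity_alignment_no_calls(self):
        pair = make_pair("ACGT" * 50, "ACGT" * 50)
        assert scan_pair(pair, RATES, CFG) == []

    def test_two_planted_inversions_far_apart(self, rng):
        bases = list("ACGT")
        hits = 0
        for _ in range(8):
            blocks = ["".join(rng.choice(bases, size=120)) for _ in range(3)]
            segs = []
            while len(segs) < 2:
                seg = "".join(rng.choice(bases, size=12))
                if sum(x != y for x, y in zip(seg, reverse_complement(seg))) >= 4:
                    segs.append(seg)
            a = blocks[0] + segs[0] + blocks[1] + segs[1] + blocks[2]
            b = (
                blocks[0]
                + reverse_complement(segs[0])
                + blocks[1]
                + reverse_complement(segs[1])
                + blocks[2]
            )
            pair = global_affine_align(a, b)
            calls = scan_pair(pair, RATES, CFG)
            starts = {c.interval_a.start for c in calls}
            want = {len(blocks[0]), len(blocks[0]) + 12 + len(blocks[1])}
            hits += sum(
                any(abs(s - w) <= 3 for s in starts) for w in want
            )
        assert hits >= 12, "two inversions 100+ bp apart are called separately"

    def test_row_symmetry(self, rng):
        for _ in range(6):
            a, b, _ = plant_inversion_pair(rng, length=10)
            pair = global_affine_align(a, b)
            fwd = scan_pair(pair, RATES, CFG)
            rev = scan_pair(pair.swapped(), RATES, CFG)
            assert len(fwd) == len(rev)
            for cf, cr in zip(fwd, rev):
                assert (cf.interval_a.start, cf.interval_a.end) == (
                    cr.interval_b.start,
                    cr.interval_b.end,
                )
                assert cf.length_bp == cr.length_bp

    def test_deterministic(self, rng):
        a, b, _ = plant_inversion_pair(rng, length=15)
        pair = global_affine_align(a, b)
        first = scan_pair(pair, RATES, CFG)
        second = scan_pair(pair, RATES, CFG)
        assert [(c.interval_a, c.interval_b, c.criterion) for c in first] == [
            (c.interval_a, c.interval_b, c.criterion) for c in second
        ]
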