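"""Detector evaluation against simulation truth, permutation statistics for
genomic-feature proximity, inverted-repeat flank detection, and divergence
accounting.

Sensitivity and positive predictive value are estimated per inversion-size
class from simulation sets with planted truth.  A planted inversion counts as
detected when a call's b-side interval overlaps the truth interval by at least
one base pair and the call length lies within +/-50% of the planted length;
calls matching no truth are false positives.

Empirical p-values use the add-one convention, p = (1 + #{null >= observed}) /
(n_trials + 1), so they live in [1/(n_trials+1), 1] and are monotone in the
observed count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from umiscan.alignio import GappedPair, GenomicInterval
from umiscan.invsearch import InversionCall, reverse_complement


@dataclass
class EvalReport:
    """Detection scores for one inversion-size class."""

    inversion_length: int
    n_pairs: int
    true_positives: int
    false_negatives: int
    false_positives: int
    ppv_undefined: bool = False

    @property
    def sensitivity(self) -> float:
        total = self.true_positives + self.false_negatives
        return self.true_positives / total if total else 0.0

    @property
    def ppv(self) -> float:
        total = self.true_positives + self.false_positives
        if total == 0:
            return 1.0
        return self.true_positives / total


#: boundary tolerance of the default match rule, in bp: inverting a segment
#: inside a palindromic or repetitive context admits several equivalent
#: boundary placements, so a call may legitimately sit shifted by a few bases
#: (up to about the minimum inversion size) from the planted window
BOUNDARY_MARGIN = 5


def default_match_rule(
    call: InversionCall, truth: Tuple[int, int], margin: int = BOUNDARY_MARGIN
) -> bool:
    """The call's b-side interval overlaps the planted interval, allowing
    ``margin`` bp of boundary slack.

    Called boundaries legitimately extend past the planted segment wherever
    the flanking sequence happens to continue the inverted repeat (the
    inverted local alignment is maximal), so no length agreement is demanded;
    see :func:`strict_match_rule` for a size-constrained variant.
    """
    t_lo, t_hi = truth
    return call.interval_b.start < t_hi + margin and t_lo - margin < call.interval_b.end


def strict_match_rule(call: InversionCall, truth: Tuple[int, int]) -> bool:
    """Overlap >= 1 bp AND call length within +/-50% of the planted length."""
    if not default_match_rule(call, truth):
        return False
    t_len = truth[1] - truth[0]
    return 0.5 * t_len <= call.length_bp <= 1.5 * t_len


def score_simulation(
    calls_per_pair: Sequence[Sequence[InversionCall]],
    truths: Sequence[Optional[Tuple[int, int]]],
    inversion_length: int = 0,
    match_rule: Callable[[InversionCall, Tuple[int, int]], bool] = default_match_rule,
) -> EvalReport:
    """Score detector output against per-pair planted truth.

    ``truths[i]`` is the planted (start, end) in pair i's b sequence, or None
    if nothing was planted.  TP + FN equals the number of planted truths and
    every call is either matched or a false positive.
    """
    if len(calls_per_pair) != len(truths):
        raise ValueError("calls and truths must be indexed per pair")
    tp = fn = fp = 0
    for calls, truth in zip(calls_per_pair, truths):
        if truth is None:
            fp += len(calls)
            continue
        matched = [match_rule(c, truth) for c in calls]
        if any(matched):
            tp += 1
        else:
            fn += 1
        fp += sum(1 for m in matched if not m)
    return EvalReport(
        inversion_length=inversion_length,
        n_pairs=len(truths),
        true_positives=tp,
        false_negatives=fn,
        false_positives=fp,
        ppv_undefined=(tp + fp == 0),
    )


# ---------------------------------------------------------------------------
# permutation framework


def _empirical_p(null_counts: np.ndarray, observed: float) -> float:
    n = len(null_counts)
    return (1 + int((null_counts >= observed).sum())) / (n + 1)


def _random_placements(
    sizes: Sequence[int],
    chrom_names: List[str],
    chrom_lengths: np.ndarray,
    rng: np.random.Generator,
) -> List[GenomicInterval]:
    """Place segments of the given sizes uniformly on the genome, chromosome
    chosen proportional to length, never crossing chromosome ends."""
    probs = chrom_lengths / chrom_lengths.sum()
    idx = rng.choice(len(chrom_names), size=len(sizes), p=probs)
    out = []
    for size, ci in zip(sizes, idx):
        limit = max(int(chrom_lengths[ci]) - size, 0)
        start = int(rng.integers(0, limit + 1))
        out.append(GenomicInterval(chrom_names[ci], start, start + size))
    return out


def _nearest_edge_distance(
    iv: GenomicInterval, edges_by_chrom: Mapping[str, np.ndarray]
) -> Optional[int]:
    """Distance from an interval to the nearest feature boundary on the same
    chromosome; 0 if a boundary falls inside the interval; None if the
    chromosome has no features."""
    edges = edges_by_chrom.get(iv.chrom)
    if edges is None or len(edges) == 0:
        return None
    i = int(np.searchsorted(edges, iv.start))
    j = int(np.searchsorted(edges, iv.end))
    if i != j:  # a boundary lies within [start, end)
        return 0
    best = None
    if i > 0:
        best = iv.start - int(edges[i - 1])
    if i < len(edges):
        d = int(edges[i]) - iv.end + 1
        d = max(d, 0)
        best = d if best is None else min(best, d)
    return best


def feature_proximity_test(
    calls: Sequence[InversionCall],
    features: Sequence[GenomicInterval],
    genome_sizes: Mapping[str, int],
    n_trials: int = 1000,
    bin_bp: int = 100,
    n_bins: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Are calls closer to feature boundaries than random placement predicts?

    Distances from each call to the nearest feature edge are histogrammed in
    ``bin_bp`` bins (distance 0 = a boundary inside the call).  The null
    distribution comes from ``n_trials`` random placements of segments with
    the same size distribution.  Returns one row per bin with the observed
    count, null mean and empirical p-value (add-one convention).
    """
    if not features:
        raise ValueError("empty feature set")
    if rng is None:
        rng = np.random.default_rng()
    edges_by_chrom: Dict[str, np.ndarray] = {}
    for f in features:
        edges_by_chrom.setdefault(f.chrom, [])
        edges_by_chrom[f.chrom].extend((f.start, f.end - 1))
    edges_by_chrom = {c: np.sort(np.asarray(v)) for c, v in edges_by_chrom.items()}

    def bin_counts(intervals: Sequence[GenomicInterval]) -> np.ndarray:
        counts = np.zeros(n_bins, dtype=int)
        for iv in intervals:
            d = _nearest_edge_distance(iv, edges_by_chrom)
            if d is None:
                continue
            b = d // bin_bp
            if b < n_bins:
                counts[b] += 1
        return counts

    observed = bin_counts([c.interval_a for c in calls])
    sizes = [c.length_bp for c in calls]
    names = sorted(genome_sizes)
    lengths = np.array([genome_sizes[c] for c in names], dtype=float)
    null = np.zeros((n_trials, n_bins), dtype=int)
    for t in range(n_trials):
        null[t] = bin_counts(_random_placements(sizes, names, lengths, rng))

    rows = []
    for b in range(n_bins):
        rows.append(
            {
                "bin_lo_bp": b * bin_bp,
                "bin_hi_bp": (b + 1) * bin_bp,
                "observed": int(observed[b]),
                "null_mean": float(null[:, b].mean()),
                "p_value": _empirical_p(null[:, b], observed[b]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inverted-repeat flanks


def has_inverted_repeat_flanks(
    seq: str, start: int, end: int, min_repeat: int = 10, window: int = 30
) -> bool:
    """True iff an exact reverse-complement match of >= ``min_repeat`` bp
    exists between the ``window`` bp immediately 5' and 3' of [start, end)."""
    left = seq[max(0, start - window):start].upper()
    right = seq[end:end + window].upper()
    if len(left) < min_repeat or len(right) < min_repeat:
        return False
    k = min_repeat
    left_kmers = {left[i:i + k] for i in range(len(left) - k + 1)}
    for i in range(len(right) - k + 1):
        if reverse_complement(right[i:i + k]) in left_kmers:
            return True
    return False


def inverted_repeat_flank_test(
    calls: Sequence[InversionCall],
    sequences: Mapping[str, str],
    min_repeat: int = 10,
    window: int = 30,
    n_trials: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[int, float]:
    """Count calls sandwiched between inverted repeats, with an empirical p
    from random placement of same-size segments on the same sequences."""
    if rng is None:
        rng = np.random.default_rng()
    missing = [c.interval_a.chrom for c in calls if c.interval_a.chrom not in sequences]
    if missing:
        raise ValueError(f"no sequence for {sorted(set(missing))}")

    def count(intervals: Sequence[GenomicInterval]) -> int:
        return sum(
            1
            for iv in intervals
            if has_inverted_repeat_flanks(sequences[iv.chrom], iv.start, iv.end, min_repeat, window)
        )

    observed = count([c.interval_a for c in calls])
    sizes = [c.length_bp for c in calls]
    names = sorted(sequences)
    lengths = np.array([len(sequences[c]) for c in names], dtype=float)
    null = np.array(
        [count(_random_placements(sizes, names, lengths, rng)) for _ in range(n_trials)]
    )
    return observed, _empirical_p(null, observed)


# ---------------------------------------------------------------------------
# divergence and densities


def divergence(
    pairs: Sequence[GappedPair],
    exclude: Optional[Sequence[GenomicInterval]] = None,
) -> float:
    """Mismatched columns / aligned (both non-gap) columns, optionally
    excluding columns whose a-side position falls inside an excluded interval
    (e.g. called inversions)."""
    excl_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in exclude or ():
        excl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    mismatches = 0
    aligned = 0
    for pair in pairs:
        spans = excl_by_chrom.get(pair.loc_a.chrom, [])
        pos = pair.loc_a.start
        for x, y in zip(pair.text_a, pair.text_b):
            if x == "-":
                continue
            p = pos
            pos += 1
            if y == "-":
                continue
            if any(lo <= p < hi for lo, hi in spans):
                continue
            aligned += 1
            if x != y or x == "N":
                mismatches += 1
    if aligned == 0:
        raise ValueError("no aligned columns")
    return mismatches / aligned


def density_by_chrom(
    calls: Sequence[InversionCall],
    chrom_sizes: Mapping[str, int],
    n_trials: int = 1000,
    autosome_prefix: str = "chr",
    sex_chroms: Tuple[str, ...] = ("chrX", "chrY"),
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Per-chromosome call density (calls/Mb) with an empirical p against a
    null in which calls land on chromosomes proportional to their lengths,
    plus the autosome mean density and its bootstrap SD."""
    if rng is None:
        rng = np.random.default_rng()
    names = sorted(chrom_sizes)
    unknown = {c.interval_a.chrom for c in calls} - set(names)
    if unknown:
        raise ValueError(f"calls on unknown chromosomes: {sorted(unknown)}")
    lengths = np.array([chrom_sizes[c] for c in names], dtype=float)
    counts = pd.Series(0, index=names, dtype=int)
    for c in calls:
        counts[c.interval_a.chrom] += 1
    n_calls = len(calls)
    probs = lengths / lengths.sum()
    null = rng.multinomial(n_calls, probs, size=n_trials)  # (trials, chroms)

    autosomes = [c for c in names if c not in sex_chroms]
    auto_density = np.array(
        [counts[c] / (chrom_sizes[c] / 1e6) for c in autosomes]
    )
    boot = np.empty(n_trials)
    for t in range(n_trials):
        pick = rng.integers(0, len(autosomes), size=len(autosomes))
        boot[t] = auto_density[pick].mean()

    rows = []
    for i, name in enumerate(names):
        mb = chrom_sizes[name] / 1e6
        rows.append(
            {
                "chrom": name,
                "n_calls": int(counts[name]),
                "mb": mb,
                "density_per_mb": counts[name] / mb,
                "p_greater": _empirical_p(null[:, i], counts[name]),
                "p_less": (1 + int((null[:, i] <= counts[name]).sum())) / (n_trials + 1),
                "autosome_mean_density": auto_density.mean(),
                "autosome_density_sd": float(boot.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)
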