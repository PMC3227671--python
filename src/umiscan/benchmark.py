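"""Simulation-based validation of the detector: sensitivity, false-positive
rate and PPV per planted-inversion size class, plus synthetic quartet fixtures
for the lineage-assignment rule.

The study conditions mirror the human-chimpanzee validation design: pairs of
sequences diverged to a realized difference density of ~0.0100 per site
(mismatches plus gap blocks), one fixed-length inversion planted per pair, the
scan run at p_d = 0.0100 / p_g = 0.00150 under either the human-chimp base
composition or the AT-exclusive composition.  Sequence length is reduced to
1,500 bp per pair to keep a full study on one CPU in minutes; planted-inversion
recovery is insensitive to the flank length (the candidate window spans ~100
columns around the signature either way), which :mod:`tests.test_acceptance`
spot-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2

from umiscan.diffscan import RateParams, SIMULATION_RATES
from umiscan.evalstats import EvalReport, score_simulation
from umiscan.evosim import (
    AT_EXCLUSIVE_COMPOSITION,
    HUMAN_CHIMP_COMPOSITION,
    SimConfig,
    evolve_sequence,
    make_simulation_set,
)
from umiscan.invsearch import DetectorConfig, reverse_complement, scan_pair
from umiscan.pairalign import star_multi_align
from umiscan.phyloprofile import assign_lineage

STANDARD_SIZES = (5, 6, 10, 20, 50)
AT_SIZES = (5, 50)
DEFAULT_ROOT_LENGTH = 1500


def _class_seed(master: int, label: str) -> int:
    import zlib

    ss = np.random.SeedSequence([int(master), zlib.crc32(label.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SizeClassResult:
    inversion_length: int
    at_exclusive: bool
    report: EvalReport
    aligned_columns: int

    @property
    def sensitivity(self) -> float:
        return self.report.sensitivity


def run_size_class(
    inversion_length: int,
    n_pairs: int = 1000,
    root_length: int = DEFAULT_ROOT_LENGTH,
    at_exclusive: bool = False,
    seed: int = 0,
    rates: Tuple[float, float] = SIMULATION_RATES,
    detector: Optional[DetectorConfig] = None,
) -> SizeClassResult:
    """Simulate one size class, realign, scan, and score against truth."""
    detector = detector or DetectorConfig()
    cfg = SimConfig(
        root_length=root_length,
        inversion_length=inversion_length,
        n_pairs=n_pairs,
        seed=seed,
        base_comp=AT_EXCLUSIVE_COMPOSITION if at_exclusive else HUMAN_CHIMP_COMPOSITION,
    )
    rate_params = RateParams(*rates)
    calls, truths = [], []
    aligned_columns = 0
    for sim, pair in make_simulation_set(cfg):
        calls.append(scan_pair(pair, rate_params, detector))
        truths.append((sim.truth_start, sim.truth_end))
        aligned_columns += len(pair)
    report = score_simulation(calls, truths, inversion_length)
    return SizeClassResult(inversion_length, at_exclusive, report, aligned_columns)


def run_study(
    seed: int,
    n_pairs: int = 1000,
    root_length: int = DEFAULT_ROOT_LENGTH,
    standard_sizes: Sequence[int] = STANDARD_SIZES,
    at_sizes: Sequence[int] = AT_SIZES,
) -> Dict[str, SizeClassResult]:
    """The full validation study: every standard and AT-exclusive size class."""
    out: Dict[str, SizeClassResult] = {}
    for L in standard_sizes:
        label = f"std{L}"
        out[label] = run_size_class(L, n_pairs, root_length, False, _class_seed(seed, label))
    for L in at_sizes:
        label = f"at{L}"
        out[label] = run_size_class(L, n_pairs, root_length, True, _class_seed(seed, label))
    return out


def poisson_rate_lower_bound(observed: int, alpha: float = 0.01) -> float:
    """One-sided (1 - alpha) lower confidence bound on a Poisson mean.

    The observed count is consistent with a hypothesized rate R (one-sided
    test at level alpha) exactly when this bound is <= R.
    """
    if observed == 0:
        return 0.0
    return float(chi2.ppf(alpha, 2 * observed) / 2.0)


def false_positive_rate_per(
    results: Sequence[SizeClassResult],
    per_pairs: Optional[int] = None,
    per_bp: Optional[int] = None,
    alpha: float = 0.01,
) -> Tuple[int, float]:
    """Pool false positives over size classes and extrapolate.

    Returns (observed FP count, one-sided lower confidence bound of the rate
    on the requested scale: per ``per_pairs`` simulated pairs or per ``per_bp``
    alignment columns).
    """
    fp = sum(r.report.false_positives for r in results)
    bound = poisson_rate_lower_bound(fp, alpha)
    if per_pairs is not None:
        n = sum(r.report.n_pairs for r in results)
        return fp, bound / n * per_pairs
    if per_bp is not None:
        cols = sum(r.aligned_columns for r in results)
        return fp, bound / cols * per_bp
    raise ValueError("specify per_pairs or per_bp")


def pooled_ppv(results: Sequence[SizeClassResult]) -> float:
    tp = sum(r.report.true_positives for r in results)
    fp = sum(r.report.false_positives for r in results)
    return tp / (tp + fp) if tp + fp else 1.0


# ---------------------------------------------------------------------------
# quartet fixtures for lineage assignment

#: branch lengths (substitutions/site) of the ((human, chimp), gorilla,
#: orangutan) fixture tree.  All pairwise flank divergences are kept at
#: human-chimpanzee-like levels (~0.007-0.015), the regime the +-1/+-3
#: difference-count thresholds of the lineage rule assume; at much deeper
#: outgroup divergence the rule is expected to return 'unresolved' more often.
QUARTET_BRANCHES = {
    "human": 0.0035,
    "chimpanzee": 0.0035,
    "hc_ancestor": 0.002,
    "gorilla": 0.005,
    "orangutan": 0.008,
}


def simulate_lineage_fixture(
    branch: str,
    rng: np.random.Generator,
    root_length: int = 200,
    inversion_length: int = 15,
) -> Tuple[List[str], List[str], Tuple[int, int]]:
    """A 4-species alignment fixture with an inversion planted on one branch.

    ``branch`` is 'human', 'chimpanzee', 'human_gorilla' or
    'chimpanzee_gorilla' (the latter two plant the same inverted state in two
    species, emulating incomplete lineage sorting).  Flank divergence follows
    great-ape levels; indels are disabled so orthologous coordinates coincide
    across species and the planted window is known exactly.
    Returns (names, sequences, human-coordinate window of the inversion).
    """
    cfg = SimConfig(root_length=root_length, indel_sub_ratio=0.0)
    root = evolve_sequence(
        "".join(rng.choice(list("ACGT"), size=root_length, p=cfg.freqs_acgt)),
        cfg, 0.0, rng,
    )
    hc_anc = evolve_sequence(root, cfg, QUARTET_BRANCHES["hc_ancestor"], rng)
    seqs = {
        "human": evolve_sequence(hc_anc, cfg, QUARTET_BRANCHES["human"], rng),
        "chimpanzee": evolve_sequence(hc_anc, cfg, QUARTET_BRANCHES["chimpanzee"], rng),
        "gorilla": evolve_sequence(root, cfg, QUARTET_BRANCHES["gorilla"], rng),
        "orangutan": evolve_sequence(root, cfg, QUARTET_BRANCHES["orangutan"], rng),
    }
    lo = (root_length - inversion_length) // 2
    hi = lo + inversion_length
    targets = {
        "human": ("human",),
        "chimpanzee": ("chimpanzee",),
        "human_gorilla": ("human", "gorilla"),
        "chimpanzee_gorilla": ("chimpanzee", "gorilla"),
    }[branch]
    for species in targets:
        s = seqs[species]
        seqs[species] = s[:lo] + reverse_complement(s[lo:hi]) + s[hi:]
    names = ["human", "chimpanzee", "gorilla", "orangutan"]
    return names, [seqs[n] for n in names], (lo, hi)


def lineage_recovery_rate(
    n_fixtures: int,
    seed: int,
    branches: Sequence[str] = ("human", "chimpanzee", "human_gorilla", "chimpanzee_gorilla"),
) -> float:
    """Fraction of synthetic quartet fixtures whose planted branch is
    recovered by star alignment + the lineage rule."""
    rng = np.random.default_rng(seed)
    correct = 0
    for i in range(n_fixtures):
        branch = branches[i % len(branches)]
        names, seqs, (lo, hi) = simulate_lineage_fixture(branch, rng)
        msa = star_multi_align(seqs, names, reference_index=0)
        ref = msa.row("human")
        cols = [c for c, ch in enumerate(ref) if ch != "-"]
        window = (cols[lo], cols[hi - 1] + 1)
        call = assign_lineage(msa, window)
        correct += call.value == branch
    return correct / n_fixtures
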