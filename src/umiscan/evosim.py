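"""Simulation of diverged sequence pairs with planted ultramicro inversions.

A random root sequence is drawn from a stated base composition and evolved
independently down two branches under HKY85 substitution with discrete-gamma
rate heterogeneity, plus insertions/deletions whose lengths follow a bounded
Lavalette distribution (the convention of the Indelible simulator family).
A fixed-length segment of one descendant is then reverse-complemented at a
uniformly random position, the truth interval is recorded, and the ungapped
pair is re-aligned with :mod:`umiscan.pairalign` for scanning.

The default divergence emulates the human-chimpanzee condition: it is
calibrated so that the realized per-site density of mismatches plus gap blocks
in the re-aligned pairs is approximately 0.0100 (the scan operating point for
the simulated condition), which puts the gap-block density near 0.00150 given
the 0.159 indel/substitution event ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, List, Optional, Tuple

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from umiscan.alignio import GappedPair
from umiscan.pairalign import AlignScoring, DEFAULT_SCORING, global_affine_align

#: internal base order for rate matrices and integer-coded sequences
BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

#: base composition of the human-chimpanzee alignment condition, (g_A, g_T, g_C, g_G)
HUMAN_CHIMP_COMPOSITION = (0.289, 0.304, 0.203, 0.204)
#: composition of the AT-exclusive condition
AT_EXCLUSIVE_COMPOSITION = (0.5, 0.5, 0.0, 0.0)

#: total substitutions per site between the two descendants, calibrated so the
#: realized mismatch + gap-block density after re-alignment is ~0.0100
DEFAULT_SUBS_PER_SITE = 0.0090


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the pair simulator.

    ``base_comp`` is ordered (g_A, g_T, g_C, g_G).  ``subs_per_site`` is the
    expected number of substitutions per site separating the two descendants
    (split equally over the two branches).  ``tstv`` is the HKY kappa
    parameter.  ``inversion_length`` is the fixed planted-segment length.
    """

    root_length: int = 5000
    base_comp: Tuple[float, float, float, float] = HUMAN_CHIMP_COMPOSITION
    tstv: float = 1.75
    subs_per_site: float = DEFAULT_SUBS_PER_SITE
    indel_sub_ratio: float = 0.159
    gamma_shape: float = 0.65
    gamma_categories: int = 5
    lavalette_a: float = 2.0
    lavalette_max: int = 50
    inversion_length: int = 10
    n_pairs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_comp) - 1.0) > 1e-9:
            raise ValueError("base_comp must sum to 1")
        if min(self.base_comp) < 0:
            raise ValueError("base_comp entries must be >= 0")
        if self.subs_per_site < 0 or self.indel_sub_ratio < 0:
            raise ValueError("rates must be non-negative")
        if not 5 <= self.inversion_length <= 125:
            raise ValueError("inversion_length must lie in [5, 125]")

    @property
    def freqs_acgt(self) -> np.ndarray:
        """Composition reordered to the internal A,C,G,T convention."""
        ga, gt, gc, gg = self.base_comp
        return np.array([ga, gc, gg, gt], dtype=float)


@dataclass
class SimPair:
    """One simulated pair; the truth interval locates the planted inversion in
    ``seq_b`` (0-based half-open), or is None before planting."""

    seq_a: str
    seq_b: str
    truth_start: Optional[int] = None
    truth_end: Optional[int] = None
    inversion_length: Optional[int] = None


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# substitution model


def hky_rate_matrix(base_comp: Tuple[float, float, float, float], tstv: float) -> np.ndarray:
    """HKY85 instantaneous rate matrix (rows/cols in A,C,G,T order),
    normalized to one expected substitution per unit branch length.

    ``tstv`` is the kappa parameter multiplying transition rates (A<->G,
    C<->T).  Zero-frequency bases are excluded from the state space: their
    rows/columns are zero and normalization runs over the remaining states
    (the AT-exclusive condition reduces to a two-state A<->T chain).
    """
    ga, gt, gc, gg = base_comp
    pi = np.array([ga, gc, gg, gt], dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("base composition must sum to 1")
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        if pi[i] == 0:
            continue
        for j in range(4):
            if i == j or pi[j] == 0:
                continue
            Q[i, j] = pi[j] * (tstv if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise ValueError("degenerate composition: no substitutions possible")
    return Q / scale


def discrete_gamma_rates(shape: float, categories: int) -> np.ndarray:
    """Mean rates of the equal-probability discrete-gamma categories
    (mean-of-bin discretization; the category means average exactly to 1)."""
    if shape <= 0 or categories < 1:
        raise ValueError("shape must be > 0 and categories >= 1")
    if categories == 1:
        return np.ones(1)
    # quantile boundaries of Gamma(shape, rate=shape); mean within each bin via
    # the regularized incomplete gamma of shape+1
    probs = np.arange(1, categories) / categories
    bounds = _gamma_dist.ppf(probs, shape, scale=1.0 / shape)
    upper = np.concatenate([gammainc(shape + 1, bounds * shape), [1.0]])
    lower = np.concatenate([[0.0], gammainc(shape + 1, bounds * shape)])
    rates = categories * (upper - lower)
    return rates / rates.mean()


def sample_gamma_category_rates(
    shape: float, categories: int, rng: np.random.Generator, n_sites: int = 1
) -> np.ndarray:
    """Per-site rate multipliers: each site is assigned one of the
    equal-probability discrete-gamma category means."""
    rates = discrete_gamma_rates(shape, categories)
    return rates[rng.integers(0, categories, size=n_sites)]


# ---------------------------------------------------------------------------
# indel lengths


def lavalette_pmf(a: float, max_len: int) -> np.ndarray:
    """Normalized Lavalette mass function over lengths 1..max_len:
    P(l) ∝ (l * M / (M - l + 1)) ** (-a)."""
    if a <= 0 or max_len < 1:
        raise ValueError("require a > 0 and max_len >= 1")
    l = np.arange(1, max_len + 1, dtype=float)
    w = (l * max_len / (max_len - l + 1.0)) ** (-a)
    return w / w.sum()


def lavalette_sample(
    a: float, max_len: int, rng: np.random.Generator, size: Optional[int] = None
) -> np.ndarray:
    """Indel length(s) drawn from the bounded Lavalette distribution."""
    pmf = lavalette_pmf(a, max_len)
    return rng.choice(np.arange(1, max_len + 1), size=size, p=pmf)


# ---------------------------------------------------------------------------
# branch evolution


def _sample_root(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=cfg.root_length, p=cfg.freqs_acgt)


def _evolve_branch(
    seq: np.ndarray,
    cat_idx: np.ndarray,
    trans_probs: np.ndarray,
    cfg: SimConfig,
    t: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve an integer-coded sequence along one branch of length ``t``
    (expected substitutions per site).

    Substitutions are applied exactly by sampling each descendant base from the
    HKY transition matrix of the site's rate category; indel events (Poisson,
    ``indel_sub_ratio * t`` per site) are then applied sequentially with
    Lavalette lengths, insertions and deletions equally likely.  Insertion
    content is drawn from the stationary composition.
    """
    # substitutions: cum[site] = cumulative transition probabilities
    cum = np.cumsum(trans_probs[cat_idx, seq, :], axis=1)
    u = rng.random(len(seq))
    new = (u[:, None] > cum).sum(axis=1).astype(np.int8)

    n_events = rng.poisson(cfg.indel_sub_ratio * t * len(seq))
    s = new
    for _ in range(n_events):
        length = int(lavalette_sample(cfg.lavalette_a, cfg.lavalette_max, rng))
        if rng.random() < 0.5 and len(s) > length:  # deletion
            pos = int(rng.integers(0, len(s) - length + 1))
            s = np.concatenate([s[:pos], s[pos + length:]])
        else:  # insertion after a uniform position
            pos = int(rng.integers(0, len(s) + 1))
            ins = rng.choice(4, size=length, p=cfg.freqs_acgt)
            s = np.concatenate([s[:pos], ins, s[pos:]])
    return s


def _to_str(seq: np.ndarray) -> str:
    return _BASE_ARR[seq].tobytes().decode("ascii")


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def evolve_sequence(
    seq: str, cfg: SimConfig, branch_length: float, rng: np.random.Generator
) -> str:
    """Evolve an explicit sequence along one branch of the given length
    (expected substitutions per site), under the model in ``cfg``.

    Multi-species fixtures (e.g. for phylogenetic profiling) are composed by
    chaining this along the branches of a species tree.
    """
    arr = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence must be over A,C,G,T")
    rates = discrete_gamma_rates(cfg.gamma_shape, cfg.gamma_categories)
    cat_idx = rng.integers(0, cfg.gamma_categories, size=len(arr))
    Q = hky_rate_matrix(cfg.base_comp, cfg.tstv)
    trans_probs = np.stack([expm(Q * branch_length * r) for r in rates])
    out = _evolve_branch(arr.astype(np.int8), cat_idx, trans_probs, cfg, branch_length, rng)
    return _to_str(out)


def evolve_pair(cfg: SimConfig, rng: np.random.Generator) -> SimPair:
    """One diverged (pre-inversion) pair.

    The root is drawn i.i.d. from ``base_comp``; per-site gamma categories are
    drawn once at the root and shared by both branches; each branch carries
    ``subs_per_site / 2`` expected substitutions per site.
    """
    root = _sample_root(cfg, rng)
    cat_idx = rng.integers(0, cfg.gamma_categories, size=len(root))
    rates = discrete_gamma_rates(cfg.gamma_shape, cfg.gamma_categories)
    Q = hky_rate_matrix(cfg.base_comp, cfg.tstv)
    t = cfg.subs_per_site / 2.0
    trans_probs = np.stack([expm(Q * t * r) for r in rates])
    # zero-frequency states never occur in root/insertions; their rows are identity
    seq_a = _evolve_branch(root, cat_idx, trans_probs, cfg, t, rng)
    seq_b = _evolve_branch(root, cat_idx, trans_probs, cfg, t, rng)
    return SimPair(_to_str(seq_a), _to_str(seq_b))


def plant_inversion(sim: SimPair, length: int, rng: np.random.Generator) -> SimPair:
    """Reverse-complement a uniformly placed segment of ``seq_b`` and record
    the truth interval.  Planting twice at the same position is an involution."""
    if length > len(sim.seq_b):
        raise ValueError("inversion longer than sequence")
    start = int(rng.integers(0, len(sim.seq_b) - length + 1))
    seq_b = sim.seq_b[:start] + _revcomp(sim.seq_b[start:start + length]) + sim.seq_b[start + length:]
    return SimPair(sim.seq_a, seq_b, truth_start=start, truth_end=start + length,
                   inversion_length=length)


def make_simulation_set(
    cfg: SimConfig,
    scoring: AlignScoring = DEFAULT_SCORING,
) -> Iterator[Tuple[SimPair, GappedPair]]:
    """Yield ``cfg.n_pairs`` simulated pairs, each with one planted inversion
    of ``cfg.inversion_length`` and its re-aligned :class:`GappedPair`.
    Fully reproducible from ``cfg.seed``."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_pairs)
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        sim = plant_inversion(evolve_pair(cfg, rng), cfg.inversion_length, rng)
        pair = global_affine_align(sim.seq_a, sim.seq_b, scoring,
                                   id_a=f"simA{i}", id_b=f"simB{i}")
        yield sim, pair
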