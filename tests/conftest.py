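"""Shared fixtures: deterministic RNGs and small simulated alignments."""

import numpy as np
import pytest

from umiscan.alignio import GappedPair, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20110308)


def make_pair(text_a: str, text_b: str, chrom_a="chrA", chrom_b="chrB", start_a=0, start_b=0):
    """Build a GappedPair from two gapped texts with synthetic coordinates."""
    ua = len(text_a) - text_a.count("-")
    ub = len(text_b) - text_b.count("-")
    return GappedPair(
        text_a,
        text_b,
        GenomicInterval(chrom_a, start_a, start_a + ua),
        GenomicInterval(chrom_b, start_b, start_b + ub),
        id="fixture",
    )


def random_gapped_pair(rng, ncols=60, gap_rate=0.08):
    """Random valid gapped pair: no column is a gap in both rows."""
    rows = [[], []]
    for _ in range(ncols):
        which = rng.random()
        if which < gap_rate:
            rows[0].append("-")
            rows[1].append(rng.choice(list("ACGT")))
        elif which < 2 * gap_rate:
            rows[0].append(rng.choice(list("ACGT")))
            rows[1].append("-")
        else:
            x = rng.choice(list("ACGT"))
            y = x if rng.random() < 0.9 else rng.choice(list("ACGT"))
            rows[0].append(x)
            rows[1].append(y)
    return make_pair("".join(rows[0]), "".join(rows[1]))
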