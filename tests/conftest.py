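"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately take naive routes — truncated double-Poisson
convolution for Skellam quantities, exact rational hypergeometric
enumeration for Fisher tests, a per-offset rescan for PSSM maxima — so
they share no code path with the implementations they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from skelldiff.genomic_io import GenomicInterval, ReadAlignments


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def poisson_pmf_vec(mu: float, kmax: int) -> np.ndarray:
    ks = np.arange(kmax + 1)
    with np.errstate(divide="ignore"):
        logp = ks * np.log(mu) - mu - np.array(
            [math.lgamma(k + 1) for k in ks]
        ) if mu > 0 else np.where(ks == 0, 0.0, -np.inf)
    return np.exp(logp)


def skellam_pmf_oracle(k: int, mu1: float, mu2: float, kmax: int = 400) -> float:
    """P(X - Y = k) by direct convolution of two truncated Poisson pmfs."""
    px = poisson_pmf_vec(mu1, kmax)
    py = poisson_pmf_vec(mu2, kmax)
    total = 0.0
    for y in range(kmax + 1):
        x = k + y
        if 0 <= x <= kmax:
            total += px[x] * py[y]
    return total


def skellam_tail_oracle(
    d: int, mu1: float, mu2: float, alternative: str, kmax: int = 400
) -> float:
    """One-sided tail by summing the convolution over the outer product."""
    px = poisson_pmf_vec(mu1, kmax)
    py = poisson_pmf_vec(mu2, kmax)
    joint = np.outer(px, py)
    x, y = np.meshgrid(np.arange(kmax + 1), np.arange(kmax + 1), indexing="ij")
    diff = x - y
    mask = diff <= d if alternative == "less" else diff >= d
    return float(joint[mask].sum())


def fisher_enum_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact rational
    arithmetic (probability-mass ordering, ties exact)."""
    n, r, col = a + b + c + d, a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    weights = [
        math.comb(r, k) * math.comb(n - r, col - k) for k in range(lo, hi + 1)
    ]
    w_obs = weights[a - lo]
    return float(Fraction(sum(w for w in weights if w <= w_obs), sum(weights)))


def naive_pssm_rescan(region: str, matrix: np.ndarray, both_strands: bool = True):
    """Per-offset O(n*w) maximum log-odds score, written independently."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = matrix.shape[1]
    strands = [region.upper()]
    if both_strands:
        strands.append("".join(comp[b] for b in reversed(region.upper())))
    best = -np.inf
    for seq in strands:
        for off in range(len(seq) - w + 1):
            window = seq[off : off + w]
            if "N" in window:
                continue
            score = sum(matrix[idx[b], j] for j, b in enumerate(window))
            best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def small_genome() -> dict:
    return {"chr1": 100_000, "chr2": 50_000}


@pytest.fixture
def uniform_reads(small_genome) -> ReadAlignments:
    rng = np.random.default_rng(0)
    positions = {
        c: np.sort(rng.integers(0, L, size=L // 100))
        for c, L in small_genome.items()
    }
    return ReadAlignments("uniform", positions, small_genome)


def make_reads(positions_by_chrom: dict, genome: dict, sample="s") -> ReadAlignments:
    return ReadAlignments(
        sample,
        {c: np.asarray(v, dtype=np.int64) for c, v in positions_by_chrom.items()},
        genome,
    )


@pytest.fixture
def iv():
    """Shorthand interval constructor."""
    return GenomicInterval
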