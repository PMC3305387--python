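"""Co-localization and depletion statistics between peak sets.

Two binding sites are considered overlapping when their peak centers are
within a threshold (default 2 kb, inclusive) of each other.  Fisher exact
tests operate on explicit boolean flag vectors over a declared universe:
the contingency construction is the caller's responsibility and therefore
auditable, since published overlap p-values depend entirely on the
universe chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .genomic_io import GenomicInterval, ReadAlignments
from .skellam_diff import _null_means, skellam_tail_logp

_LN10 = np.log(10.0)


@dataclass
class OverlapResult:
    """A 2x2 overlap contingency table with its Fisher exact test."""

    both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float          # sample odds ratio ad/bc; inf when bc = 0
    p_two_sided: float
    threshold: int | None = None
    universe_size: int = 0
    degenerate: bool = False   # a margin is all-zero: p = 1, OR undefined


def _centers_by_chrom(peaks: Sequence[GenomicInterval]) -> Dict[str, np.ndarray]:
    by: Dict[str, List[int]] = {}
    for p in peaks:
        by.setdefault(p.chrom, []).append(p.center)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by.items()}


def centers_within(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    threshold: int = 2000,
) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Match peaks of a to peaks of b by center distance <= threshold (bp).

    Returns a boolean flag per a-peak and the list of matched index pairs
    (a_index, index of the nearest qualifying b-center).  Implemented as
    a sorted sweep via searchsorted.
    """
    b_centers = _centers_by_chrom(b)
    b_index: Dict[str, np.ndarray] = {}
    for chrom in b_centers:
        order = np.argsort([p.center for i, p in enumerate(b) if p.chrom == chrom])
        idx = np.asarray([i for i, p in enumerate(b) if p.chrom == chrom])
        b_index[chrom] = idx[order]
    flags = np.zeros(len(a), dtype=bool)
    pairs: List[Tuple[int, int]] = []
    for i, pk in enumerate(a):
        centers = b_centers.get(pk.chrom)
        if centers is None or centers.size == 0:
            continue
        c = pk.center
        j = np.searchsorted(centers, c)
        best, best_d = -1, threshold + 1
        for cand in (j - 1, j):
            if 0 <= cand < centers.size:
                d = abs(int(centers[cand]) - c)
                if d < best_d:
                    best, best_d = cand, d
        if best >= 0 and best_d <= threshold:
            flags[i] = True
            pairs.append((i, int(b_index[pk.chrom][best])))
    return flags, pairs


def fisher_overlap_test(
    a_flags: Sequence[bool],
    b_flags: Sequence[bool],
    threshold: int | None = None,
) -> OverlapResult:
    """Two-sided Fisher exact test of association between two flag vectors.

    The two-sided p sums hypergeometric probabilities no larger than that
    of the observed table (probability-mass ordering); the reported odds
    ratio is the sample odds ratio ad/bc (infinity when bc = 0).
    Degenerate margins (an all-zero row or column) give p = 1 with the
    odds ratio flagged undefined.
    """
    af = np.asarray(a_flags, dtype=bool)
    bf = np.asarray(b_flags, dtype=bool)
    if af.shape != bf.shape:
        raise ValueError("flag vectors must have equal length")
    both = int(np.sum(af & bf))
    a_only = int(np.sum(af & ~bf))
    b_only = int(np.sum(~af & bf))
    neither = int(np.sum(~af & ~bf))
    n = af.size
    if (both + a_only == 0 or b_only + neither == 0
            or both + b_only == 0 or a_only + neither == 0):
        return OverlapResult(both, a_only, b_only, neither,
                             odds_ratio=float("nan"), p_two_sided=1.0,
                             threshold=threshold, universe_size=n,
                             degenerate=True)
    p = fisher_two_sided(both, a_only, b_only, neither)
    bc = a_only * b_only
    odds = float("inf") if bc == 0 else (both * neither) / bc
    return OverlapResult(both, a_only, b_only, neither,
                         odds_ratio=odds, p_two_sided=p,
                         threshold=threshold, universe_size=n)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Conditional on the margins, the count a follows a hypergeometric
    distribution; the two-sided p sums the probabilities of all tables
    whose probability does not exceed the observed table's (ties
    included, with a 1e-12 relative tolerance absorbing float rounding
    of exactly tied rational probabilities).
    """
    n = a + b + c + d
    r, col = a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r, col)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-12)].sum()))


def depletion_score(
    count_before: int, count_after: int, scale: float = 1.0,
    direction: str = "loss",
) -> float:
    """-log10 Skellam tail p-value of the before/after count difference.

    direction="loss" scores the significance of a *decrease* after the
    perturbation (upper tail of D = before - after under the scaled
    null); "gain" scores an increase.  Computed in log space, so scores
    remain finite far beyond float underflow of the p-value itself.
    """
    if count_before < 0 or count_after < 0:
        raise ValueError("counts must be nonnegative")
    if count_before == 0 and count_after == 0:
        return 0.0
    mu1, mu2 = _null_means(float(count_before), float(count_after), scale)
    alt = "greater" if direction == "loss" else "less"
    lp = float(skellam_tail_logp(count_before - count_after, mu1, mu2, alt)[0])
    return max(0.0, -lp / _LN10)


def cutoff_sensitivity(
    calls_a: Dict[float, Sequence[GenomicInterval]],
    calls_b: Dict[float, Sequence[GenomicInterval]],
    threshold: int = 2000,
):
    """Percentage of a-peaks (per cutoff) matching b-peaks (per cutoff).

    Entry (i, j) is the percentage of a-peaks at cutoff i whose centers
    lie within ``threshold`` of a b-peak at cutoff j; entries with an
    empty a-set are missing (NaN), not 0.  Returns a pandas DataFrame
    indexed by a-cutoffs with b-cutoffs as columns.
    """
    import pandas as pd

    a_cuts = sorted(calls_a, reverse=True)
    b_cuts = sorted(calls_b, reverse=True)
    mat = np.full((len(a_cuts), len(b_cuts)), np.nan)
    for i, ca in enumerate(a_cuts):
        peaks_a = list(calls_a[ca])
        if not peaks_a:
            continue
        for j, cb in enumerate(b_cuts):
            flags, _ = centers_within(peaks_a, list(calls_b[cb]), threshold)
            mat[i, j] = 100.0 * flags.mean()
    return pd.DataFrame(mat, index=a_cuts, columns=b_cuts)


@dataclass
class ProfileMatrix:
    """Read counts in flank bins around anchor peak centers."""

    values: np.ndarray          # rows: anchors; columns: flank bins
    bin_size: int
    flank: int
    truncated: np.ndarray       # rows clipped at a chromosome edge

    @property
    def offsets(self) -> np.ndarray:
        """Left edge of each column relative to the anchor center."""
        return np.arange(-self.flank, self.flank, self.bin_size)


def aggregate_profile(
    reads: ReadAlignments,
    anchors: Sequence[GenomicInterval],
    flank: int = 5000,
    bin_size: int = 100,
) -> ProfileMatrix:
    """Read-density matrix around anchor centers (counts per bin).

    Row r, column c counts reads with position in
    [center_r - flank + c*bin, center_r - flank + (c+1)*bin).  Rows whose
    flank extends past a chromosome edge are zero-padded and flagged.
    Reads near two anchors are counted in both rows.
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    n_cols = 2 * flank // bin_size
    values = np.zeros((len(anchors), n_cols), dtype=np.int64)
    truncated = np.zeros(len(anchors), dtype=bool)
    for r, anchor in enumerate(anchors):
        pos = reads.chrom_positions(anchor.chrom)
        c = anchor.center
        left, right = c - flank, c + flank
        truncated[r] = left < 0 or right > reads.genome.get(anchor.chrom, right)
        lo = np.searchsorted(pos, left, side="left")
        hi = np.searchsorted(pos, right, side="left")
        if hi > lo:
            cols = (pos[lo:hi] - left) // bin_size
            values[r] = np.bincount(cols, minlength=n_cols)[:n_cols]
    return ProfileMatrix(values, bin_size, flank, truncated)


def nearest_distance_transform(
    sites: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
) -> np.ndarray:
    """Signed-log distance from each reference center to its nearest site.

    For reference center S and nearest site center P on the same
    chromosome the value is sign(P - S) * log10 |P - S|; coincident
    centers map to 0 by convention; references on chromosomes without
    sites yield NaN (missing).
    """
    site_centers = _centers_by_chrom(sites)
    out = np.full(len(reference), np.nan)
    for i, ref in enumerate(reference):
        centers = site_centers.get(ref.chrom)
        if centers is None or centers.size == 0:
            continue
        s = ref.center
        j = np.searchsorted(centers, s)
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < centers.size:
                d = int(centers[cand]) - s
                if best is None or abs(d) < abs(best):
                    best = d
        if best == 0:
            out[i] = 0.0
        else:
            out[i] = np.sign(best) * np.log10(abs(best))
    return out


def fraction_overlapping(
    peaks: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
) -> float:
    """Fraction of peaks intersecting at least one region (1 bp suffices)."""
    if not peaks:
        raise ValueError("empty query set")
    merged: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    by: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        by.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom, spans in by.items():
        spans.sort()
        starts, ends = [], []
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = s, e
        starts.append(cur_s)
        ends.append(cur_e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    hits = 0
    for p in peaks:
        if p.chrom not in merged:
            continue
        starts, ends = merged[p.chrom]
        j = np.searchsorted(starts, p.end, side="left") - 1
        if j >= 0 and ends[j] > p.start:
            hits += 1
    return hits / len(peaks)
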