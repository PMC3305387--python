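"""Background equalization of a paired sample set by order statistics.

Two ChIP-seq samples of the same factor before/after a perturbation share
a large background of bins unaffected by the perturbation; only a
minority of bins carry (differential) enrichment.  Sorting the binned
counts of each sample and plotting the ratio of their partial sums
against the quantile cutoff yields a curve that is flat (constant ratio)
over the background quantiles and bends where enriched bins start
entering the sums.  The ratio at that critical quantile is the background
scale factor linking the two samples.

The critical point is found by fitting an ordinary least-squares line to
the curve over the 10th–60th quantile span and scanning upward for the
first point deviating from the fit by more than 3 residual standard
deviations.

Conventions: bins empty in both samples are excluded before sorting;
chromosomes are pooled genome-wide before computing order statistics; the
reported ``scale_factor`` is the ratio partial_sum(A)/partial_sum(B) at
the critical quantile, i.e. the multiplier that maps sample B's counts
onto sample A's scale.  ``background_ratio`` (= 1/scale_factor) is the
estimated background depth of B relative to A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .genomic_io import ReadAlignments


@dataclass
class BinnedCounts:
    """Per-chromosome read counts at a fixed bin width for one sample."""

    sample_id: str
    bin_size: int
    counts: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, v in self.counts.items():
            v = np.asarray(v)
            if np.any(v < 0):
                raise ValueError(f"negative counts on {chrom}")
            self.counts[chrom] = v.astype(np.int64)

    @property
    def total(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))

    def pooled(self, chrom_order: Sequence[str] | None = None) -> np.ndarray:
        order = sorted(self.counts) if chrom_order is None else chrom_order
        return np.concatenate([self.counts[c] for c in order])


@dataclass
class NormalizationResult:
    """Partial-sum ratio curve, critical quantile, and scale factor."""

    quantiles: np.ndarray          # strictly increasing in (0, 1]
    ratios: np.ndarray             # r(q) = psum_A(q) / psum_B(q)
    critical_quantile: float
    scale_factor: float            # multiplier applied onto sample B
    slope: float
    intercept: float
    residual_sd: float
    n_background_bins: int

    @property
    def background_ratio(self) -> float:
        """Estimated background depth of sample B relative to sample A."""
        return 1.0 / self.scale_factor

    def to_dict(self) -> dict:
        return {
            "critical_quantile": self.critical_quantile,
            "scale_factor": self.scale_factor,
            "background_ratio": self.background_ratio,
            "regression": {
                "slope": self.slope,
                "intercept": self.intercept,
                "residual_sd": self.residual_sd,
            },
            "n_background_bins": self.n_background_bins,
            "ratio_curve": [
                {"q": float(q), "r": float(r)}
                for q, r in zip(self.quantiles, self.ratios)
            ],
        }


def bin_counts(reads: ReadAlignments, bin_size: int = 1000) -> BinnedCounts:
    """Tally reads into fixed-width bins by their stored 5' position."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    counts = {}
    for chrom, length in reads.genome.items():
        n_bins = -(-length // bin_size)
        counts[chrom] = np.bincount(
            reads.chrom_positions(chrom) // bin_size, minlength=n_bins
        )
    return BinnedCounts(reads.sample_id, bin_size, counts)


def default_quantile_grid(n: int = 100) -> np.ndarray:
    """Evenly spaced quantiles 1/n, 2/n, ..., 1."""
    return np.arange(1, n + 1) / n


def partial_sum_ratio_curve(
    a: BinnedCounts,
    b: BinnedCounts,
    quantile_grid: Sequence[float] | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Ratio of partial sums of order statistics as a function of quantile.

    Bins of each sample are sorted ascending independently; for each
    quantile q, r(q) = (sum of the lowest floor(qN) order statistics of
    a) / (same for b).  Bins with zero counts in both samples are dropped
    beforehand; grid points with zero denominator are dropped from the
    curve.
    """
    if a.bin_size != b.bin_size:
        raise ValueError("bin sizes differ between samples")
    if set(a.counts) != set(b.counts):
        raise ValueError("chromosome sets differ between samples")
    grid = default_quantile_grid() if quantile_grid is None else np.asarray(quantile_grid, float)
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("quantile grid must lie in (0, 1]")

    order = sorted(a.counts)
    va, vb = a.pooled(order), b.pooled(order)
    keep = (va > 0) | (vb > 0)
    va, vb = va[keep], vb[keep]
    if va.sum() == 0 or vb.sum() == 0:
        raise ValueError("no background signal: one sample has zero reads")
    n = va.size
    ca = np.cumsum(np.sort(va), dtype=np.float64)
    cb = np.cumsum(np.sort(vb), dtype=np.float64)

    qs: List[float] = []
    rs: List[float] = []
    for q in np.sort(grid):
        m = int(np.floor(q * n))
        if m < 1:
            continue
        if cb[m - 1] == 0:
            continue
        qs.append(float(q))
        rs.append(float(ca[m - 1] / cb[m - 1]))
    return np.asarray(qs), np.asarray(rs)


def find_critical_point(
    quantiles: np.ndarray,
    ratios: np.ndarray,
    fit_range: Tuple[float, float] = (0.10, 0.60),
    n_sd: float = 3.0,
) -> Tuple[float, float, Tuple[float, float, float]]:
    """Locate where the ratio curve departs from its background linearity.

    An OLS line is fit to the curve points with quantile inside
    ``fit_range``; scanning the points above the range in increasing
    quantile, deviation onset is the first point whose residual exceeds
    ``n_sd`` residual standard deviations, and the critical point is the
    point immediately preceding it — the last quantile still consistent
    with the background line, so the reported ratio excludes the first
    contaminated grid step.  If no point deviates, the largest grid
    quantile is returned (the curve is background-linear throughout).

    Returns (critical_quantile, scale_factor, (slope, intercept, residual_sd)).
    """
    quantiles = np.asarray(quantiles, float)
    ratios = np.asarray(ratios, float)
    if quantiles.size < 10 or quantiles.max() <= fit_range[1]:
        raise ValueError("curve must have >= 10 points spanning beyond the fit range")
    in_fit = (quantiles >= fit_range[0]) & (quantiles <= fit_range[1])
    if in_fit.sum() < 3:
        raise ValueError("fewer than 3 curve points inside the regression range")
    fit = stats.linregress(quantiles[in_fit], ratios[in_fit])
    resid = ratios[in_fit] - (fit.slope * quantiles[in_fit] + fit.intercept)
    dof = max(1, int(in_fit.sum()) - 2)
    sd = float(np.sqrt(np.sum(resid**2) / dof))

    above_idx = np.nonzero(quantiles > fit_range[1])[0]
    q_star = float(quantiles[-1])
    s = float(ratios[-1])
    for i in above_idx:
        if abs(ratios[i] - (fit.slope * quantiles[i] + fit.intercept)) > n_sd * sd:
            j = max(0, i - 1)
            q_star, s = float(quantiles[j]), float(ratios[j])
            break
    return q_star, s, (float(fit.slope), float(fit.intercept), sd)


def normalize_pair(
    a: ReadAlignments,
    b: ReadAlignments,
    bin_size: int = 1000,
    quantile_grid: Sequence[float] | None = None,
) -> NormalizationResult:
    """Equalize the background of sample b onto sample a.

    Composition of bin_counts, partial_sum_ratio_curve and
    find_critical_point; the returned scale_factor thereafter multiplies
    sample b's counts in all downstream tests.
    """
    ba = bin_counts(a, bin_size)
    bb = bin_counts(b, bin_size)
    qs, rs = partial_sum_ratio_curve(ba, bb, quantile_grid)
    q_star, s, (slope, intercept, sd) = find_critical_point(qs, rs)
    order = sorted(ba.counts)
    n_bg = int(((ba.pooled(order) > 0) | (bb.pooled(order) > 0)).sum())
    return NormalizationResult(
        quantiles=qs,
        ratios=rs,
        critical_quantile=q_star,
        scale_factor=s,
        slope=slope,
        intercept=intercept,
        residual_sd=sd,
        n_background_bins=int(np.floor(q_star * n_bg)),
    )
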