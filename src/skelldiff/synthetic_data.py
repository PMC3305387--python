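"""Synthetic paired ChIP-seq data with known ground truth.

The generator emulates the statistical structure the analysis assumes:
two paired samples whose background bins are Poisson with rates differing
by a global scale factor, a minority of bins carrying localized
enrichment, a planted subset of enriched regions depleted in the second
sample, and a genome sequence with CpG islands and embedded instances of
GC-rich motifs.

Background reads are uniform (homogeneous Poisson) per chromosome; the
analysis needs only exchangeable background bins and uniformity keeps the
analytic checks tractable.  A single integer master seed is split
deterministically into per-component substreams so every stage is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .genomic_io import GenomicInterval, GenomeSequence, ReadAlignments

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside every simulated dataset."""

    seed: int
    scale_factor: float = 1.0
    peaks: List[GenomicInterval] = field(default_factory=list)
    peak_folds: List[float] = field(default_factory=list)
    depleted_flags: List[bool] = field(default_factory=list)
    motif_placements: List[Tuple[GenomicInterval, int, str]] = field(default_factory=list)
    cpg_islands: List[GenomicInterval] = field(default_factory=list)
    gene_intervals: List[GenomicInterval] = field(default_factory=list)

    @property
    def depleted_peaks(self) -> List[GenomicInterval]:
        return [p for p, d in zip(self.peaks, self.depleted_flags) if d]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "scale_factor": self.scale_factor,
            "peaks": [
                {
                    "chrom": p.chrom,
                    "start": p.start,
                    "end": p.end,
                    "fold": f,
                    "depleted": bool(d),
                }
                for p, f, d in zip(self.peaks, self.peak_folds, self.depleted_flags)
            ],
            "motif_placements": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                 "motif": m, "strand": s}
                for iv, m, s in self.motif_placements
            ],
            "cpg_islands": [
                {"chrom": p.chrom, "start": p.start, "end": p.end}
                for p in self.cpg_islands
            ],
            "n_genes": len(self.gene_intervals),
        }


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-component RNG derived from the master seed.

    Uses a CRC of the component label (process-stable, unlike ``hash``)
    so each stage draws from its own reproducible stream.
    """
    import zlib

    child = np.random.SeedSequence([seed, zlib.crc32(label.encode()) % (2**31)])
    return np.random.default_rng(child)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    item_len: int,
    length: int,
    forbidden: Sequence[Tuple[int, int]] = (),
    max_tries: int = 10000,
) -> List[int]:
    """Draw n non-overlapping start positions avoiding forbidden spans."""
    taken = list(forbidden)
    starts: List[int] = []
    tries = 0
    while len(starts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} items of length {item_len} "
                f"in {length} bp without overlap"
            )
        s = int(rng.integers(0, length - item_len + 1))
        if all(s + item_len <= a or s >= b for a, b in taken):
            taken.append((s, s + item_len))
            starts.append(s)
    return starts


def simulate_genome(
    length: int = 1_000_000,
    n_islands: int = 20,
    island_len: int = 1000,
    island_gc: float = 0.70,
    background_gc: float = 0.40,
    motifs: Sequence[str] = (),
    sites_per_motif: int = 0,
    seed: int = 0,
    chrom: str = "chr1",
) -> Tuple[GenomeSequence, SimulationTruth]:
    """Simulate one chromosome with CpG islands and embedded motif instances.

    Bases are i.i.d. at the stated GC fraction (islands at ``island_gc``,
    elsewhere ``background_gc``); islands are non-overlapping; each motif
    consensus is embedded verbatim at recorded positions, half of them
    inside islands, with random strand.
    """
    if motifs and island_gc <= background_gc:
        pass  # gc ordering only matters when islands exist
    if n_islands > 0 and island_gc <= background_gc:
        raise ValueError("island_gc must exceed background_gc")
    for m in motifs:
        if not set(m) <= set("ACGT"):
            raise ValueError(f"motif {m!r} not over ACGT")
    if n_islands * island_len > length // 2:
        raise ValueError("islands do not fit in the requested genome length")

    rng = _substream(seed, "genome")
    codes = _random_bases(rng, length, background_gc)

    island_starts = sorted(
        _place_nonoverlapping(rng, n_islands, island_len, length)
    )
    islands = [GenomicInterval(chrom, s, s + island_len) for s in island_starts]
    for s in island_starts:
        codes[s : s + island_len] = _random_bases(rng, island_len, island_gc)

    truth = SimulationTruth(seed=seed, cpg_islands=islands)
    occupied: List[Tuple[int, int]] = []
    for motif_id, consensus in enumerate(motifs):
        w = len(consensus)
        n_in = sites_per_motif // 2
        n_out = sites_per_motif - n_in
        placements: List[int] = []
        # half inside islands (one site max per island slot), half outside
        island_pool = [s for s in island_starts]
        rng.shuffle(island_pool)
        for s in island_pool[:n_in]:
            for _ in range(100):
                off = int(rng.integers(0, island_len - w + 1))
                cand = s + off
                if all(cand + w <= a or cand >= b for a, b in occupied):
                    placements.append(cand)
                    occupied.append((cand, cand + w))
                    break
            else:
                raise ValueError("could not place motif inside an island")
        out_starts = _place_nonoverlapping(
            rng, n_out, w, length,
            forbidden=[(s, s + island_len) for s in island_starts] + occupied,
        )
        placements.extend(out_starts)
        for p in placements:
            strand = "+" if rng.random() < 0.5 else "-"
            inst = consensus if strand == "+" else reverse_complement(consensus)
            codes[p : p + w] = [("ACGT").index(b) for b in inst]
            occupied.append((p, p + w))
            truth.motif_placements.append(
                (GenomicInterval(chrom, p, p + w, strand), motif_id, strand)
            )
    seq = "".join(_BASES[codes])
    return {chrom: seq}, truth


def simulate_paired_reads(
    genome: Dict[str, int],
    n_peaks: int = 200,
    peak_len: int = 1000,
    enrichment_fold: float = 10.0,
    depleted_fraction: float = 0.5,
    background_rate: float = 0.02,
    scale_factor: float = 1.0,
    n_reads_a: int = 200_000,
    seed: int = 0,
    retained_enrichment: float = 0.0,
    peak_positions: Sequence[GenomicInterval] | None = None,
    depleted_flags: Sequence[bool] | None = None,
) -> Tuple[ReadAlignments, ReadAlignments, SimulationTruth]:
    """Draw a paired (reference, knockdown) read set with planted peaks.

    Sample A draws exactly ``n_reads_a`` positions from a mixture of a
    uniform background and uniform-within-peak enrichment components whose
    relative weights follow ``background_rate`` and ``enrichment_fold``
    (each peak's total density is ``fold`` times background).  Sample B is
    drawn from the same mixture with (i) every component's expectation
    multiplied by ``scale_factor`` and (ii) the enrichment component of
    depleted peaks reduced to ``retained_enrichment`` of its A-value
    (default 0: total loss).  Peak identities and depletion flags are
    recorded in the returned truth.
    """
    if background_rate <= 0 or enrichment_fold <= 1 or scale_factor <= 0:
        raise ValueError("rates must be positive and enrichment_fold > 1")
    if not 0 <= depleted_fraction <= 1:
        raise ValueError("depleted_fraction must lie in [0,1]")
    rng = _substream(seed, "reads")

    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    if peak_positions is not None:
        peaks = list(peak_positions)
        n_peaks = len(peaks)
    else:
        peaks = []
        # apportion peaks to chromosomes by length
        alloc = rng.multinomial(n_peaks, lengths / lengths.sum())
        for c, k in zip(chroms, alloc):
            if peak_len * k * 3 > genome[c] and k > 0:
                raise ValueError("peaks overflow the genome")
            starts = _place_nonoverlapping(rng, int(k), peak_len, genome[c])
            peaks.extend(GenomicInterval(c, s, s + peak_len) for s in sorted(starts))
    if depleted_flags is not None:
        depleted = np.asarray(depleted_flags, dtype=bool)
        if depleted.size != n_peaks:
            raise ValueError("depleted_flags length must match the peak count")
    else:
        n_dep = int(round(depleted_fraction * n_peaks))
        dep_idx = rng.choice(n_peaks, size=n_dep, replace=False) if n_peaks else []
        depleted = np.zeros(n_peaks, dtype=bool)
        depleted[list(dep_idx)] = True

    # mixture weights: background per chrom, plus one enrichment component
    # per peak carrying (fold-1) x background density over its span
    bg_w = background_rate * lengths.astype(float)
    peak_w = np.array(
        [(enrichment_fold - 1.0) * background_rate * len(p) for p in peaks]
    )
    weights_a = np.concatenate([bg_w, peak_w]) if n_peaks else bg_w
    weights_a = weights_a / weights_a.sum()

    def draw(weights: np.ndarray, n_reads: int) -> Dict[str, np.ndarray]:
        counts = rng.multinomial(n_reads, weights / weights.sum())
        pos: Dict[str, List[np.ndarray]] = {c: [] for c in chroms}
        for i, c in enumerate(chroms):
            if counts[i]:
                pos[c].append(rng.integers(0, genome[c], size=counts[i]))
        for j, p in enumerate(peaks):
            k = counts[len(chroms) + j]
            if k:
                pos[p.chrom].append(rng.integers(p.start, p.end, size=k))
        return {
            c: np.sort(np.concatenate(v)) if v else np.empty(0, dtype=np.int64)
            for c, v in pos.items()
        }

    pos_a = draw(weights_a, n_reads_a)

    scale_b = np.concatenate(
        [
            np.full(len(chroms), scale_factor),
            np.where(depleted, scale_factor * retained_enrichment, scale_factor)
            if n_peaks
            else np.empty(0),
        ]
    )
    exp_b = weights_a * n_reads_a * scale_b
    n_reads_b = int(rng.poisson(exp_b.sum()))
    pos_b = draw(exp_b, n_reads_b)

    a = ReadAlignments("sampleA", pos_a, dict(genome))
    b = ReadAlignments("sampleB", pos_b, dict(genome))
    truth = SimulationTruth(
        seed=seed,
        scale_factor=scale_factor,
        peaks=peaks,
        peak_folds=[enrichment_fold] * n_peaks,
        depleted_flags=list(map(bool, depleted)),
    )
    return a, b, truth


def simulate_gene_annotation(
    genome: Dict[str, int],
    n_genes: int = 1000,
    density_gradient: Dict[str, float] | None = None,
    gene_len: int = 10_000,
    seed: int = 0,
) -> List[GenomicInterval]:
    """Place gene intervals with per-chromosome start probability weights."""
    rng = _substream(seed, "genes")
    chroms = list(genome)
    if density_gradient is None:
        weights = np.array([genome[c] for c in chroms], dtype=float)
    else:
        weights = np.array([density_gradient.get(c, 0.0) for c in chroms])
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    counts = rng.multinomial(n_genes, weights / weights.sum())
    genes: List[GenomicInterval] = []
    for c, k in zip(chroms, counts):
        max_start = max(1, genome[c] - gene_len)
        starts = np.sort(rng.integers(0, max_start, size=k))
        genes.extend(
            GenomicInterval(c, int(s), int(min(s + gene_len, genome[c])))
            for s in starts
        )
    return genes


def simulate_feature_dataset(
    n_per_class: int = 500,
    class_separation: Sequence[float] = (1.0, 1.0, 0.05),
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Two Gaussian clouds in the 3-feature space (motif1, motif2, CpG).

    Returns a list of SiteFeatures with labels ``pcl_dependent`` (shifted
    by ``class_separation``) and ``pcl_independent`` (centered at zero).
    """
    from .sequence_features import SiteFeatures

    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")
    rng = _substream(seed, "features")
    sep = np.asarray(class_separation, dtype=float)
    if sep.shape != (3,):
        raise ValueError("class_separation must give 3 effect sizes")
    base = rng.normal(0.0, noise_sd, size=(2 * n_per_class, 3))
    base[:n_per_class] += sep
    labels = ["pcl_dependent"] * n_per_class + ["pcl_independent"] * n_per_class
    return [
        SiteFeatures(
            site=None,
            motif1_max=float(x[0]),
            motif2_max=float(x[1]),
            cpg_density=float(x[2]),
            label=lab,
        )
        for x, lab in zip(base, labels)
    ]
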