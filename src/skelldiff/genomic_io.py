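"""Reading and writing the genomic file formats used throughout the pipeline.

All coordinates are 0-based half-open (BED convention) internally; SAM's
1-based positions are converted on ingest.  A read is represented by its
5'-most mapped position only: for a minus-strand alignment that is the last
aligned base (``reference_end - 1`` in half-open terms).  Duplicate reads
are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pysam

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval; the universal coordinate record."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReadAlignments:
    """5'-end positions of uniquely mapped single-end reads for one sample.

    ``reads`` maps chromosome -> sorted int array of 5' positions; strand
    information is kept alongside only where a caller needs it (the
    statistics downstream are strand-agnostic).
    """

    sample_id: str
    positions: Dict[str, np.ndarray]
    genome: Dict[str, int]
    shift: int = 0

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            if chrom not in self.genome:
                raise ValueError(f"chromosome {chrom!r} missing from genome table")
            pos = np.asarray(pos, dtype=np.int64)
            if self.shift:
                pos = np.clip(pos + self.shift, 0, self.genome[chrom] - 1)
            pos = np.sort(pos)
            if pos.size and (pos[0] < 0 or pos[-1] >= self.genome[chrom]):
                raise ValueError(
                    f"read position outside [0, {self.genome[chrom]}) on {chrom}"
                )
            self.positions[chrom] = pos

    @property
    def n_reads(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.empty(0, dtype=np.int64))


# GenomeSequence is a plain dict chrom -> uppercase ACGTN string.
GenomeSequence = Dict[str, str]


def _bed_read_records(path: str | Path) -> Iterable[Tuple[int, List[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_alignments(
    path: str | Path,
    fmt: str = "bed",
    genome: Dict[str, int] | None = None,
    sample_id: str | None = None,
    shift: int = 0,
) -> ReadAlignments:
    """Load mapped reads from a SAM file or a BED file of read placements.

    One record per uniquely mapped read; unmapped/secondary/supplementary
    SAM records are skipped.  The stored coordinate is the 5' end of the
    read: BED/SAM ``start`` on the plus strand, ``end - 1`` on the minus
    strand.

    Parameters
    ----------
    genome : chrom -> length table.  Required for BED input and for SAM
        files without @SQ header lines.
    shift : optional global 5'-shift in bp applied to every read (default
        0; no fragment model is assumed otherwise).
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    if fmt == "sam":
        return _read_sam(path, genome, sample_id, shift)
    if fmt == "bed":
        if genome is None:
            raise ValueError("BED read input requires a genome length table")
        return _read_bed_reads(path, genome, sample_id, shift)
    raise ValueError(f"unknown alignment format {fmt!r}")


def _read_sam(
    path: Path, genome: Dict[str, int] | None, sample_id: str, shift: int
) -> ReadAlignments:
    by_chrom: Dict[str, List[int]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        lengths = dict(zip(sam.references, sam.lengths))
        if not lengths:
            if genome is None:
                raise ValueError(
                    "SAM file has no @SQ header lines; supply a genome "
                    "table (chrom -> length) explicitly"
                )
            lengths = dict(genome)
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            pos = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            by_chrom.setdefault(rec.reference_name, []).append(pos)
    positions = {c: np.array(p, dtype=np.int64) for c, p in by_chrom.items()}
    return ReadAlignments(sample_id, positions, lengths, shift=shift)


def _read_bed_reads(
    path: Path, genome: Dict[str, int], sample_id: str, shift: int
) -> ReadAlignments:
    by_chrom: Dict[str, List[int]] = {}
    for lineno, f in _bed_read_records(path):
        if len(f) < 3:
            raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: unparsable coordinates") from exc
        if start >= end:
            raise ValueError(f"{path}: line {lineno}: start >= end")
        strand = f[5] if len(f) >= 6 else "."
        pos = end - 1 if strand == "-" else start
        by_chrom.setdefault(chrom, []).append(pos)
    positions = {c: np.array(p, dtype=np.int64) for c, p in by_chrom.items()}
    return ReadAlignments(sample_id, positions, dict(genome), shift=shift)


def read_intervals(path: str | Path) -> List[GenomicInterval]:
    """Parse a BED3/BED6 file into intervals, preserving input order."""
    out: List[GenomicInterval] = []
    for lineno, f in _bed_read_records(path):
        if len(f) < 3:
            raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: unparsable coordinates") from exc
        if start >= end:
            raise ValueError(f"{path}: line {lineno}: start >= end")
        score: float | None = None
        if len(f) >= 5 and f[4] not in ("", "."):
            score = float(f[4])
        strand = f[5] if len(f) >= 6 and f[5] in STRANDS else "."
        out.append(GenomicInterval(f[0], start, end, strand, score))
    return out


def bed_score(pvalue: float) -> int:
    """BED display score: min(1000, round(-10 log10 p))."""
    if pvalue <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(pvalue))))


def write_peaks(calls: Sequence, path: str | Path) -> None:
    """Write differential calls as BED6 (name=direction, score from p).

    Calls must be sorted by (chrom, start); unsorted input is rejected so
    downstream interval sweeps can rely on order.
    """
    keys = [(c.interval.chrom, c.interval.start) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, start) before writing")
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.direction}\t"
                f"{bed_score(c.p_skellam)}\t.\n"
            )


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}\t{iv.strand}\n")


def export_density_track(
    reads: ReadAlignments, bin_size: int = 250, path: str | Path = "density.bedGraph"
) -> None:
    """Write a bedGraph of raw read counts per fixed-width bin.

    Only nonzero bins are emitted; the sum of track values equals the read
    count of the sample for any bin width.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    with open(path, "w") as fh:
        for chrom in sorted(reads.positions):
            length = reads.genome[chrom]
            n_bins = -(-length // bin_size)
            counts = np.bincount(
                reads.chrom_positions(chrom) // bin_size, minlength=n_bins
            )
            for idx in np.nonzero(counts)[0]:
                start = int(idx) * bin_size
                end = min(start + bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{int(counts[idx])}\n")


def read_chrom_sizes(path: str | Path) -> Dict[str, int]:
    """Read a 2-column chrom-sizes TSV."""
    table: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'chrom<TAB>length'")
            table[f[0]] = int(f[1])
    return table


def write_chrom_sizes(genome: Dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def write_fasta(sequences: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into an in-memory chrom -> sequence dict."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
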