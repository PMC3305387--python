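"""End-to-end orchestration of the differential-occupancy analysis.

Stages run in a fixed order — normalize, diffcall, overlap, genedensity,
features, classify — from a single validated configuration, writing
plain-text outputs plus a JSON manifest with a config hash and per-file
checksums.  Rerunning with the same configuration reproduces
byte-identical outputs (no timestamps enter any output file).

The one-command synthetic demonstration generates a genome with CpG
islands and two planted GC-rich motifs, paired read sets with a known
background scale factor and a planted set of depleted peaks (centered on
motif instances so the sequence features genuinely separate the
condition-dependent class), a gene annotation, and a truth file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from . import genomic_io as gio
from . import synthetic_data as synth
from .gene_density import build_density_track, correlate_density
from .genomic_io import GenomicInterval, ReadAlignments
from .interval_stats import aggregate_profile, centers_within, fisher_overlap_test
from .normalization import bin_counts, default_quantile_grid, normalize_pair
from .sequence_features import (
    MarkovBackground,
    build_pssm,
    collect_instances,
    crossval_classifier,
    extract_features,
    kmer_enrichment_scan,
)
from .skellam_diff import AdjustmentParams, call_differential


@dataclass
class PipelineConfig:
    """All analysis constants and (optionally) input paths.

    Defaults equal the method's stated constants: 400-bp windows,
    p-value cutoff 1e-7, 2-kb peak-center matching, 1-Mbp density bins,
    motif lengths 6-15, 10-fold cross-validation.
    """

    # inputs (filled by the simulate stage when absent)
    reads_a: Optional[str] = None
    reads_b: Optional[str] = None
    genome_fasta: Optional[str] = None
    chrom_sizes: Optional[str] = None
    genes_bed: Optional[str] = None
    islands_bed: Optional[str] = None
    truth_json: Optional[str] = None
    # analysis constants
    window: int = 400
    step: int = 100
    cutoff: float = 1e-7
    # normalization bins deep enough for ~100+ reads/bin at the default
    # simulated depth; order-statistic curves are stable in that regime
    norm_bin: int = 10_000
    grid_points: int = 100
    overlap_threshold: int = 2000
    density_bin: int = 1_000_000
    motif_lengths: List[int] = field(default_factory=lambda: list(range(6, 16)))
    region: int = 500
    svm_folds: int = 10
    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    seed: int = 0
    # synthetic-data conditions
    sim_genome_length: int = 10_000_000
    sim_n_peaks: int = 200
    sim_peak_len: int = 1000
    sim_fold: float = 10.0
    sim_depleted_fraction: float = 0.5
    sim_scale_factor: float = 1.0
    sim_n_reads: int = 200_000
    sim_background_rate: float = 0.02
    sim_n_islands: int = 150
    sim_island_len: int = 1500
    sim_island_gc: float = 0.70
    sim_background_gc: float = 0.40
    sim_motif1: str = "CGGCGGAAGC"
    sim_motif2: str = "GCCGCGAGGCGCTG"
    sim_n_genes: int = 2000

    def validate(self) -> None:
        for name in ("window", "step", "norm_bin", "grid_points",
                     "overlap_threshold", "density_bin", "region",
                     "svm_folds", "sim_genome_length", "sim_n_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        if self.window % self.step:
            raise ValueError("window must be a multiple of step")
        if not 0 <= self.sim_depleted_fraction <= 1:
            raise ValueError("sim_depleted_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(msg: str) -> None:
    print(f"[skelldiff] {msg}", file=sys.stderr)


def simulate_dataset(cfg: PipelineConfig, outdir: str | Path) -> Dict[str, str]:
    """Generate the full synthetic dataset and write it to ``outdir``.

    Depleted peaks are centered on planted motif instances (half inside
    CpG islands); retained peaks are placed on plain background, so
    motif scores and CpG density carry real class signal downstream.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = synth._substream(cfg.seed, "scenario")

    n_dep = int(round(cfg.sim_depleted_fraction * cfg.sim_n_peaks))
    sites_per_motif = -(-n_dep // 2)
    genome_seq, seq_truth = synth.simulate_genome(
        length=cfg.sim_genome_length,
        n_islands=cfg.sim_n_islands,
        island_len=cfg.sim_island_len,
        island_gc=cfg.sim_island_gc,
        background_gc=cfg.sim_background_gc,
        motifs=[cfg.sim_motif1, cfg.sim_motif2],
        sites_per_motif=sites_per_motif,
        seed=cfg.seed,
    )
    chrom = next(iter(genome_seq))
    genome_table = {chrom: len(genome_seq[chrom])}

    # depleted peaks centered on motif placements; retained peaks on background
    placements = [iv for iv, _, _ in seq_truth.motif_placements]
    rng.shuffle(placements)
    half_len = cfg.sim_peak_len // 2
    dep_peaks: List[GenomicInterval] = []
    for iv in placements[:n_dep]:
        start = max(0, min(iv.center - half_len,
                           cfg.sim_genome_length - cfg.sim_peak_len))
        dep_peaks.append(GenomicInterval(chrom, start, start + cfg.sim_peak_len))
    forbidden = [(p.start, p.end) for p in dep_peaks] + [
        (i.start, i.end) for i in seq_truth.cpg_islands
    ]
    other_starts = synth._place_nonoverlapping(
        rng, cfg.sim_n_peaks - n_dep, cfg.sim_peak_len,
        cfg.sim_genome_length, forbidden=forbidden,
    )
    other_peaks = [
        GenomicInterval(chrom, s, s + cfg.sim_peak_len) for s in sorted(other_starts)
    ]
    peaks = dep_peaks + other_peaks
    flags = [True] * len(dep_peaks) + [False] * len(other_peaks)

    a, b, truth = synth.simulate_paired_reads(
        genome_table,
        peak_len=cfg.sim_peak_len,
        enrichment_fold=cfg.sim_fold,
        background_rate=cfg.sim_background_rate,
        scale_factor=cfg.sim_scale_factor,
        n_reads_a=cfg.sim_n_reads,
        seed=cfg.seed,
        peak_positions=peaks,
        depleted_flags=flags,
    )
    truth.motif_placements = seq_truth.motif_placements
    truth.cpg_islands = seq_truth.cpg_islands
    genes = synth.simulate_gene_annotation(
        genome_table, n_genes=cfg.sim_n_genes, seed=cfg.seed
    )
    truth.gene_intervals = genes

    paths = {
        "reads_a": str(outdir / "reads_A.bed"),
        "reads_b": str(outdir / "reads_B.bed"),
        "genome_fasta": str(outdir / "genome.fa"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
        "genes_bed": str(outdir / "genes.bed"),
        "islands_bed": str(outdir / "islands.bed"),
        "truth_json": str(outdir / "truth.json"),
    }
    _write_reads_bed(a, paths["reads_a"])
    _write_reads_bed(b, paths["reads_b"])
    gio.write_fasta(genome_seq, paths["genome_fasta"])
    gio.write_chrom_sizes(genome_table, paths["chrom_sizes"])
    gio.write_intervals(genes, paths["genes_bed"])
    gio.write_intervals(truth.cpg_islands, paths["islands_bed"])
    with open(paths["truth_json"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    for key, val in paths.items():
        setattr(cfg, key, val)
    return paths


def _write_reads_bed(reads: ReadAlignments, path: str, read_len: int = 30) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reads.positions):
            length = reads.genome[chrom]
            for i, pos in enumerate(reads.chrom_positions(chrom)):
                end = min(int(pos) + read_len, length)
                fh.write(f"{chrom}\t{pos}\t{end}\tr{i}\t0\t+\n")


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    simulate: bool = False,
    force: bool = False,
) -> dict:
    """Execute all stages and return the manifest dict."""
    cfg.validate()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not (force or simulate):
        raise ValueError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": [],
        "checksums": {},
        "counts": {},
    }

    if simulate:
        _log("stage simulate")
        simulate_dataset(cfg, outdir / "inputs")

    for key in ("reads_a", "reads_b", "chrom_sizes"):
        if getattr(cfg, key) is None:
            raise ValueError(f"missing required input {key!r}")
    genome_table = gio.read_chrom_sizes(cfg.chrom_sizes)
    a = gio.read_alignments(cfg.reads_a, "bed", genome_table, "sampleA")
    b = gio.read_alignments(cfg.reads_b, "bed", genome_table, "sampleB")
    manifest["counts"]["reads_a"] = a.n_reads
    manifest["counts"]["reads_b"] = b.n_reads

    # --- normalize -------------------------------------------------------
    _log("stage normalize")
    grid = default_quantile_grid(cfg.grid_points)
    norm = normalize_pair(a, b, cfg.norm_bin, grid)
    with open(outdir / "norm.json", "w") as fh:
        json.dump(norm.to_dict(), fh, indent=1)
    with open(outdir / "ratio_curve.tsv", "w") as fh:
        fh.write("quantile\tratio\n")
        for q, r in zip(norm.quantiles, norm.ratios):
            fh.write(f"{q:.6g}\t{r:.10g}\n")
    manifest["stages"].append("normalize")

    # --- diffcall --------------------------------------------------------
    _log("stage diffcall")
    L = float(sum(genome_table.values()))
    params = AdjustmentParams(L=L, window=cfg.window, step=cfg.step,
                              cutoff=cfg.cutoff)
    peaks, ec = call_differential(a, b, norm, params)
    gio.write_peaks(peaks, outdir / "peaks.bed")
    with open(outdir / "peaks.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tdirection\tcount_a\tcount_b\t"
                 "p_skellam\tlog10_p\tp_adjusted\tmerged_from\n")
        for p in peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.direction}\t{p.count_a}\t{p.count_b}\t"
                f"{p.p_skellam:.6g}\t{p.log10_p:.6g}\t"
                f"{p.p_adjusted:.6g}\t{p.merged_from}\n"
            )
    manifest["counts"]["peaks"] = len(peaks)
    manifest["counts"]["expected_correlation_length"] = ec
    manifest["stages"].append("diffcall")

    loss_peaks = [p.interval for p in peaks if p.direction == "loss"]

    # --- overlap / profiles ---------------------------------------------
    _log("stage overlap")
    overlap_out: dict = {}
    truth = None
    if cfg.truth_json:
        with open(cfg.truth_json) as fh:
            truth = json.load(fh)
        truth_peaks = [
            GenomicInterval(p["chrom"], p["start"], p["end"])
            for p in truth["peaks"]
        ]
        dep_flags = np.array([p["depleted"] for p in truth["peaks"]], dtype=bool)
        called_flags, _ = centers_within(
            truth_peaks, loss_peaks, cfg.overlap_threshold
        )
        fisher = fisher_overlap_test(
            dep_flags, called_flags, threshold=cfg.overlap_threshold
        )
        sens = (
            float(called_flags[dep_flags].mean()) if dep_flags.any() else np.nan
        )
        overlap_out = {
            "universe": "planted peaks",
            "n_truth_peaks": len(truth_peaks),
            "n_called_loss_peaks": len(loss_peaks),
            "sensitivity_depleted": sens,
            "fisher": {
                "both": fisher.both, "a_only": fisher.a_only,
                "b_only": fisher.b_only, "neither": fisher.neither,
                "odds_ratio": fisher.odds_ratio
                if np.isfinite(fisher.odds_ratio) else None,
                "p_two_sided": fisher.p_two_sided,
            },
        }
    with open(outdir / "overlap.json", "w") as fh:
        json.dump(overlap_out, fh, indent=1)
    anchors = loss_peaks[:500]
    if anchors:
        prof = aggregate_profile(a, anchors, flank=5000, bin_size=100)
        with open(outdir / "profile.tsv", "w") as fh:
            fh.write("\t".join(str(o) for o in prof.offsets) + "\n")
            for row in prof.values:
                fh.write("\t".join(str(int(v)) for v in row) + "\n")
    manifest["stages"].append("overlap")

    # --- gene density ----------------------------------------------------
    _log("stage genedensity")
    gd_out: dict = {}
    if cfg.genes_bed:
        genes = gio.read_intervals(cfg.genes_bed)
        ba = bin_counts(a, cfg.density_bin)
        bb = bin_counts(b, cfg.density_bin)
        track = build_density_track(
            genes, ba, bb, genome_table, norm.scale_factor, cfg.density_bin
        )
        track.frame().to_csv(outdir / "genedensity.tsv", sep="\t", index=False)
        try:
            r, r_dep, grouped = correlate_density(track.gene_counts, track.logfc)
            grouped.to_csv(outdir / "genedensity_grouped.tsv", sep="\t", index=False)
            gd_out = {"pearson_r_logfc": r, "pearson_r_depletion": r_dep,
                      "n_bins": int(np.isfinite(track.logfc).sum())}
        except ValueError:
            gd_out = {"pearson_r_logfc": None,
                      "note": "fewer than 3 informative bins"}
    with open(outdir / "genedensity.json", "w") as fh:
        json.dump(gd_out, fh, indent=1)
    manifest["stages"].append("genedensity")

    # --- sequence features ----------------------------------------------
    _log("stage features")
    feat_rows = []
    features = None
    if cfg.genome_fasta and truth is not None:
        genome_seq = gio.read_fasta(cfg.genome_fasta)
        half = cfg.region // 2
        fg = [
            genome_seq[iv.chrom][max(0, iv.center - half): iv.center + half]
            for iv in loss_peaks
        ] or [
            genome_seq[p["chrom"]][
                max(0, (p["start"] + p["end"]) // 2 - half):
                (p["start"] + p["end"]) // 2 + half
            ]
            for p in truth["peaks"] if p["depleted"]
        ]
        bg_model = MarkovBackground.train(
            list(genome_seq.values()), order=9
        )
        ranked = kmer_enrichment_scan(
            fg, bg_model, lengths=cfg.motif_lengths, top_n=3
        )
        ranked.to_csv(outdir / "motifs.tsv", sep="\t", index=False)
        pssms = []
        for target_len in (len(cfg.sim_motif1), len(cfg.sim_motif2)):
            sub = ranked[ranked["length"] == target_len]
            kmer = (sub.iloc[0]["kmer"] if not sub.empty
                    else ranked.iloc[0]["kmer"])
            inst = collect_instances(fg, kmer, max_mismatch=1)
            if len(inst) < 2:
                inst = [kmer, kmer]
            pssms.append(build_pssm(inst, name=f"motif_{target_len}"))
        truth_peaks = [
            GenomicInterval(p["chrom"], p["start"], p["end"])
            for p in truth["peaks"]
        ]
        labels = [
            "pcl_dependent" if p["depleted"] else "pcl_independent"
            for p in truth["peaks"]
        ]
        features = extract_features(
            truth_peaks, genome_seq, pssms[0], pssms[1],
            region=cfg.region, labels=labels,
        )
        with open(outdir / "features.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tmotif1_max\tmotif2_max\t"
                     "cpg_density\tlabel\n")
            for f in features:
                fh.write(
                    f"{f.site.chrom}\t{f.site.start}\t{f.site.end}\t"
                    f"{f.motif1_max:.6g}\t{f.motif2_max:.6g}\t"
                    f"{f.cpg_density:.6g}\t{f.label}\n"
                )
    manifest["stages"].append("features")

    # --- classify --------------------------------------------------------
    _log("stage classify")
    clf_out: dict = {}
    if features is not None and len(features) >= cfg.svm_folds:
        acc, fold_accs, _ = crossval_classifier(
            features, folds=cfg.svm_folds, kernel=cfg.svm_kernel,
            C=cfg.svm_c, seed=cfg.seed,
        )
        clf_out = {
            "cv_accuracy": acc,
            "fold_accuracies": [float(x) for x in fold_accs],
            "n_sites": len(features),
        }
    with open(outdir / "classify.json", "w") as fh:
        json.dump(clf_out, fh, indent=1)
    manifest["stages"].append("classify")

    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["checksums"][str(f.relative_to(outdir))] = _sha256(f)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    _log(f"done: {len(manifest['stages'])} stages")
    return manifest
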