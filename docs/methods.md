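# Methods

This note records the statistical model, the conventions chosen where
the design was genuinely open, the numerical implementation, and what
the synthetic data do and do not establish.

## Model and assumptions

Two ChIP-seq samples of the same factor are compared, a reference
(sample A) and a perturbed sample (B, e.g. after cofactor knockdown).
The model assumes that (i) read counts in genomic bins are Poisson,
(ii) a large majority of bins are background whose rates differ
between samples only by a global scale factor, and (iii) a minority of
bins carry localized enrichment, a subset of which loses that
enrichment in B. No replicate structure, overdispersion, or input
subtraction is modeled; windows are tested marginally.

## Background normalization

- Counts are binned and pooled genome-wide before sorting ("the
  background" is treated as a single population; per-chromosome
  normalization is not performed).
- Bins with zero counts in both samples are excluded: unmappable or
  empty regions carry no information and would distort quantiles.
- The ratio curve r(q) = psumA(q)/psumB(q) is evaluated on 100 evenly
  spaced quantiles by default.
- The regression uses the curve points in the [10 %, 60 %] quantile
  span (about half of all points); residual SD is taken from that fit
  with 2 degrees of freedom lost.
- **Critical-point convention.** Scanning upward from the 60th
  quantile, deviation onset is the first point whose residual exceeds
  3 SD; the reported critical point is the point *immediately before*
  it. Reading the ratio at the onset point itself would already
  include one grid step of enrichment contamination (on a ramp of
  slope β the overshoot is β/grid-resolution); the preceding point is
  the last quantile consistent with the background line. If no point
  deviates, the largest quantile is used.
- **Orientation.** `scale_factor` = r(q\*) is the multiplier applied
  onto sample B (A-over-B partial-sum ratio). `background_ratio` =
  1/scale_factor is the estimated background depth of B relative to A
  and is the quantity compared against a simulation's planted ratio.
- **Bin size.** Default 10 kb in the pipeline configuration. The
  partial-sum ratio of two Poisson samples at different rates is only
  asymptotically flat: at mean count λ per bin the curve's residual
  curvature biases the detected ratio by O(1/√λ). Empirically the
  recovery error is ≈7 % at λ = 10 and ≈2–3 % at λ ≥ 200, so bins
  should be chosen to hold ≳100 reads in the shallower sample. The
  `bin_counts` primitive accepts any bin size; the statistical test
  itself always runs on 400-bp windows and is unaffected.

## Skellam differential test

- **Null parameterization.** Under H₀ the A-count is Poisson(μ₁) and
  the B-count Poisson(μ₂) with μ₁ = s·μ₂. The pooled estimate is
  μ₂ = (k_A + k_B)/(1 + s); the scale multiplies the *rate*, never the
  counts, so both margins stay integer-valued Poisson and the test
  reduces to the classical equal-means Skellam test at s = 1.
- **Directions.** The tail primitive takes `alternative` ∈ {"less",
  "greater"} on D = k_A − k_B. The biological label "loss" (depletion
  in B) corresponds to the *upper* tail of D; "gain" to the lower
  tail. Each window is labeled with the smaller of the two one-sided
  p-values; no doubling is applied. Consequently the reported
  two-direction minimum is not itself a calibrated p-value (it is
  ≈ 2× anti-conservative); calibration statements and depletion scores
  always refer to a one-sided tail.
- **Windows.** 400 bp, step 100 bp by default ("running windows");
  windows with zero reads in both samples are skipped. Merging unions
  overlapping or bookended same-direction significant windows,
  re-tallies counts over the union from the raw reads, and recomputes
  the one-sided p there. Merged peaks are reported without
  re-thresholding (each derives from significant windows).
- **E[C]**: mean length (in windows) of maximal runs of consecutive
  significant windows at the calling cutoff, never spanning
  chromosomes, 1.0 when no run exists — a "clump" in the Poisson
  clumping heuristic is precisely a maximal run of exceedances.
- **Adjusted p**: p_adj = 1 − exp(−p·L/E[C]), clipped to [0, 1]; L
  defaults to the sum of supplied chromosome lengths. The relation is
  strictly monotone until float saturation (p·L/E[C] ≳ 37), where the
  adjusted value clamps to 1.
- **Numerics.** log-pmf via the exponentially scaled Bessel function
  `ive` (with a leading-series fallback where it underflows); tails by
  direct log-space summation over the decaying side of the lattice
  (span 20·√(μ₁+μ₂)+60 terms, truncation error < 10⁻¹⁵) and
  complementation otherwise; `log1p`/`expm1` for complements. Tail
  log-probabilities remain finite far beyond float underflow of p
  itself, which is what depletion scores use. Per-window computation
  is grouped over unique (k_A, k_B) pairs and chunked.

## Interval statistics

- Center matching is inclusive: |centerA − centerB| ≤ 2000 bp; the
  center of [start, end) is ⌊(start+end)/2⌋.
- Fisher tests take explicit boolean flag vectors over a caller-declared
  universe. Published overlap p-values depend entirely on the universe
  chosen, so the contingency construction must be auditable; raw peak
  sets are never accepted. The two-sided p uses probability-mass
  ordering with ties included (1e-12 relative tolerance absorbs float
  rounding of exactly tied rational probabilities); the sample odds
  ratio ad/bc is reported, infinite when bc = 0, undefined for
  degenerate margins (then p = 1).
- Scores are −log₁₀ p throughout.
- Aggregate profiles may double-count reads lying within the flank of
  two anchors; rows truncated at chromosome edges are zero-padded and
  flagged.
- CpG density defaults to CG-dinucleotide count/(length − 1); an
  observed/expected variant (n_CG·L/(n_C·n_G)) is available via
  `method="obs_exp"`.

## Gene density

1-Mbp disjoint bins; a gene belongs to the bin containing its start.
Log fold-change is log₂((s·k_B + 1)/(k_A + 1)) — pseudocount 1 bounds
the value at empty bins, base 2 is the field convention; bins empty in
both samples are masked. Both the raw Pearson r (density vs logfc) and
its negation (density vs depletion magnitude, positive when depletion
concentrates in gene-dense regions) are reported, plus a grouped
summary over density classes of width 10. The per-chromosome summary
uses a two-sample Wilcoxon rank-sum test of each chromosome's bins
against the pooled rest, without multiplicity correction.

## Sequence features

- **k-mer enrichment scan.** A deliberately simple discovery stage:
  exhaustive k-mer counting (lengths 6–15), expected counts from a
  Markov background model, greedy redundancy collapse (substring,
  superstring, or Hamming-1 neighbors of a higher-scoring k-mer).
  K-mers are ranked by the Poisson likelihood-ratio statistic
  G = 2(obs·ln(obs/exp) − (obs − exp)) rather than the raw log fold:
  with a tiny expectation a handful of chance occurrences of a long
  k-mer produce an enormous fold ratio, and under fold-ranking such
  spurious extensions of a true motif would absorb the motif itself in
  the collapse step. G weighs observed support, so a well-supported
  planted motif dominates. The raw log fold is reported alongside.
- **Markov background.** Requested order up to 9; auto-capped to the
  largest order at which every context is observed ≥ 10 times, with
  marginalized lower-order tables retained so k-mers shorter than the
  order stay scorable. Conditionals use pseudocount 0.5.
- **PSSM.** Column probabilities (count + 0.5)/(n + 2); log-odds base
  2 against a uniform background (independent-bases assumption);
  scanning takes the maximum over offsets and both strands; windows
  containing N score −∞ and are skipped.
- **SVM.** RBF kernel, C = 1 (the defaults of the classical e1071-style
  formulation), features standardized with training-fold statistics
  only, stratified 10-fold assignment (stratification is a variance
  reduction choice) seeded for reproducibility.

## Synthetic data

The generator emulates exactly the structure the model assumes:
uniform (homogeneous Poisson) background per chromosome, uniform
enrichment within planted peaks at a stated fold, total (or
configurable partial) loss of enrichment in depleted peaks, a global
background scale factor between samples, i.i.d. base composition with
elevated GC in non-overlapping islands, verbatim motif instances (half
inside islands), and weighted gene placement. Sample A contains exactly
the requested read count; sample B's total is a Poisson draw around its
scaled expectation. A single master seed is split into per-component
substreams (CRC-derived, process-stable), so every stage is
reproducible in isolation and end-to-end runs are byte-identical.

Default study conditions: 10-Mb genome, 2×10⁵ reads in A, 200 peaks of
1 kb at fold 10 (≈200 reads/peak), half depleted, 150 CpG islands
(GC 0.70 vs 0.40 background), one 10-mer and one 14-mer GC-rich motif.
In the one-command demonstration the depleted peaks are centered on
motif instances and retained peaks on plain background, so the three
sequence features genuinely separate the classes; with test-scale data
the classifier is expected to be near-perfect, unlike the much noisier
real-data setting.

**What passing tests do not show.** The generator has no mappability
or GC bias, no fragment-length model (reads are 5′ points; an optional
global shift is exposed but defaults to 0), no PCR duplicates, no
sequencing error, and background bins are exchangeable by
construction. Real data violate all of these to some degree; the tests
establish correctness of the machinery under its own model, not
robustness to artifacts. The `background_rate` parameter of the read
simulator acts through the component weights (background vs per-peak
enrichment mass); sample A's depth is fixed by `n_reads_a`.

Calibration of the null is checked on *disjoint* windows (step =
window) so the binomial error model applies, at a depth (μ ≈ 1000 per
window) where the discrete lattice of achievable p-values is fine
compared to the test levels; at low counts the exact test is
conservative and the achievable-level gap, not the implementation,
limits agreement. Overlapping running windows share counts and their
p-values are locally correlated — that correlation is what E[C]
absorbs in the genome-wide adjustment.

## Known limitations

- Single-end 5′-point representation only; no paired-end logic.
- The pooled-rate null loses power when the scale factor is far from 1
  (the pooled estimate absorbs part of a one-sided signal); depletion
  detection is most sensitive at matched depths.
- The normalization critical point is grid-resolution-limited and
  assumes the background curve is locally linear over the fit span.
- The k-mer scan is a stand-in for a full motif-discovery algorithm:
  it only proposes exact k-mers (plus 1-mismatch instance collection
  for PSSM building) and does not merge reverse complements.
- Fisher tests and overlap fractions are as good as the universe the
  caller supplies.
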