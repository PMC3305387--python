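"""Sequence features of binding sites: PSSMs, CpG density, k-mer
enrichment, and SVM classification.

The three features used to classify condition-dependent binding sites
are the maximum position-specific scoring-matrix (PSSM) score of each of
two motifs over the 500-bp central region of a peak, plus the region's
CpG-dinucleotide density.  Candidate motifs are found with a greedy
k-mer enrichment scan against a Markov background model of the
nucleotide composition (a deliberately simple exhaustive-counting
discovery stage: observed versus Markov-expected k-mer counts with
greedy redundancy collapse).  Classification uses a support-vector
machine with an RBF kernel under stratified 10-fold cross-validation,
features standardized from the training folds only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval, GenomeSequence
from .synthetic_data import reverse_complement

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Sequence -> int8 codes (A=0 C=1 G=2 T=3, N and others = 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.full(256, 4, dtype=np.int8)
    for b, c in _CODE.items():
        table[ord(b)] = c
    return table[arr]


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

@dataclass
class PSSM:
    """Log-odds (base 2) scoring matrix, 4 x width, versus a background."""

    matrix: np.ndarray                  # shape (4, width)
    background: np.ndarray              # base frequencies, sum 1
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.background.shape != (4,):
            raise ValueError("matrix must be 4 x width with a 4-vector background")
        probs = (2.0 ** self.matrix) * self.background[:, None]
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("columns do not invert to probability distributions")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))


def build_pssm(
    instances: Sequence[str],
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
    name: str = "motif",
) -> PSSM:
    """Build a log-odds PSSM from aligned equal-length instances.

    Column probabilities are (count + pseudocount) / (n + 4*pseudocount);
    the default background is uniform (independent bases).
    """
    if len(instances) < 2:
        raise ValueError("need at least 2 instances")
    width = len(instances[0])
    if any(len(s) != width for s in instances):
        raise ValueError("instances must have equal length")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    codes = np.stack([encode(s) for s in instances])
    if np.any(codes > 3):
        raise ValueError("instances must be over ACGT only")
    counts = np.stack(
        [np.bincount(codes[:, j], minlength=4) for j in range(width)], axis=1
    ).astype(float)
    probs = (counts + pseudocount) / (len(instances) + 4.0 * pseudocount)
    with np.errstate(divide="ignore"):
        matrix = np.log2(probs / bg[:, None])
    return PSSM(matrix, bg, name=name)


def _scan_scores(codes: np.ndarray, pssm: PSSM) -> np.ndarray:
    """Window scores over one strand; windows containing N get -inf."""
    w = pssm.width
    ext = np.vstack([pssm.matrix, np.full(w, -np.inf)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    with np.errstate(invalid="ignore"):
        return ext[windows, np.arange(w)].sum(axis=1)


def max_pssm_score(region: str, pssm: PSSM, both_strands: bool = True) -> float:
    """Maximum summed log-odds over all offsets (and optionally the
    reverse complement).  Windows containing N are skipped; -inf when no
    window is scorable."""
    if len(region) < pssm.width:
        raise ValueError("region shorter than PSSM width")
    best = np.max(_scan_scores(encode(region), pssm))
    if both_strands:
        rc = np.max(_scan_scores(encode(reverse_complement(region)), pssm))
        best = max(best, rc)
    return float(best)


# ---------------------------------------------------------------------------
# CpG density
# ---------------------------------------------------------------------------

def cpg_density(region: str, method: str = "per_bp") -> float:
    """CpG-dinucleotide density of a region.

    method="per_bp" (default): count of CG dinucleotides / (length - 1).
    method="obs_exp": observed/expected ratio n_CG * L / (n_C * n_G),
    the CpG-island convention (0 when the region lacks C or G).
    """
    if len(region) < 2:
        raise ValueError("region must have length >= 2")
    seq = region.upper()
    n_cg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
    if method == "per_bp":
        return n_cg / (len(seq) - 1)
    if method == "obs_exp":
        n_c, n_g = seq.count("C"), seq.count("G")
        if n_c == 0 or n_g == 0:
            return 0.0
        return n_cg * len(seq) / (n_c * n_g)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Markov background and k-mer enrichment scan
# ---------------------------------------------------------------------------

@dataclass
class MarkovBackground:
    """Order-m Markov model of base composition with pseudocount 0.5.

    The requested order is auto-capped to the largest order at which
    every context is observed at least ``min_context_count`` times in
    the training sequence, so sparse corpora fall back to lower orders
    gracefully.
    """

    order: int
    context_logp: np.ndarray      # marginal log prob of each m-mer context
    cond_logp: np.ndarray         # shape (4^m, 4)
    trained_on: int

    @classmethod
    def train(
        cls,
        sequences: Sequence[str] | str,
        order: int = 9,
        min_context_count: int = 10,
    ) -> "MarkovBackground":
        if isinstance(sequences, str):
            sequences = [sequences]
        coded = [encode(s) for s in sequences]
        total = sum(c.size for c in coded)
        m = order
        while m > 0:
            ctx_counts = np.zeros(4**m, dtype=np.int64)
            for c in coded:
                ids = _kmer_ids(c, m)
                if ids.size:
                    ctx_counts += np.bincount(ids, minlength=4**m)
            if ctx_counts.min() >= min_context_count:
                break
            m -= 1
        if m == 0:
            ctx_counts = np.array([total], dtype=np.int64)
        trans = np.zeros((4**m, 4), dtype=np.int64)
        for c in coded:
            if c.size <= m:
                continue
            ids = _kmer_ids(c, m + 1)
            if ids.size == 0:
                continue
            np.add.at(trans, (ids // 4, ids % 4), 1)
        cond = (trans + 0.5) / (trans.sum(axis=1, keepdims=True) + 2.0)
        ctx_p = (ctx_counts + 1.0) / (ctx_counts.sum() + len(ctx_counts))
        model = cls(
            order=m,
            context_logp=np.log(ctx_p),
            cond_logp=np.log(cond),
            trained_on=total,
        )
        # marginalized lower-order tables (context id = most recent bases
        # in the low digits), so k-mers shorter than the order stay scorable
        model._lower = {}
        for o in range(m):
            t_o = trans.reshape(4 ** (m - o), 4**o, 4).sum(axis=0)
            c_o = ctx_counts.reshape(4 ** (m - o), 4**o).sum(axis=0)
            cond_o = (t_o + 0.5) / (t_o.sum(axis=1, keepdims=True) + 2.0)
            ctx_o = (c_o + 1.0) / (c_o.sum() + c_o.size)
            model._lower[o] = (np.log(ctx_o), np.log(cond_o))
        return model

    def kmer_logp(self, codes: np.ndarray) -> np.ndarray:
        """log probability of each row of a (U, k) code matrix.

        K-mers no longer than the model order are scored from the
        marginal k-gram distribution; longer ones chain the order-m
        conditionals from the order-m context marginal.
        """
        codes = np.atleast_2d(codes)
        m = self.order
        k = codes.shape[1]
        if k <= m:
            pows = 4 ** np.arange(k - 1, -1, -1)
            ids = codes @ pows
            if k == m:
                return self.context_logp[ids]
            return self._lower[k][0][ids]
        if m == 0:
            ctx = np.zeros(codes.shape[0], dtype=np.int64)
            logp = np.zeros(codes.shape[0])
            start = 0
        else:
            pows = 4 ** np.arange(m - 1, -1, -1)
            ctx = codes[:, :m] @ pows
            logp = self.context_logp[ctx]
            start = m
        for i in range(start, k):
            logp = logp + self.cond_logp[ctx, codes[:, i]]
            if m:
                ctx = (ctx * 4 + codes[:, i]) % (4**m)
        return logp

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Draw a sequence from the model (for permutation nulls)."""
        m = self.order
        probs = np.exp(self.context_logp)
        if m == 0:
            cond = np.exp(self.cond_logp[0])
            draws = rng.choice(4, size=length, p=cond / cond.sum())
            return "".join(_BASES[i] for i in draws)
        ctx = int(rng.choice(len(probs), p=probs / probs.sum()))
        out = []
        pows = 4 ** np.arange(m - 1, -1, -1)
        seed_codes = [(ctx // int(p)) % 4 for p in pows]
        out.extend(seed_codes)
        for _ in range(length - m):
            cond = np.exp(self.cond_logp[ctx])
            b = int(rng.choice(4, p=cond / cond.sum()))
            out.append(b)
            ctx = (ctx * 4 + b) % (4**m)
        return "".join(_BASES[i] for i in out[:length])


def _kmer_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """Encode every ACGT-only k-mer window as an integer id.

    Rolling polynomial accumulation keeps memory at O(n) even for
    chromosome-scale inputs; windows containing N are dropped.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    m = n - k + 1
    ids = np.zeros(m, dtype=np.int64)
    for j in range(k):
        ids = ids * 4 + codes[j : j + m]
    bad = np.concatenate([[0], np.cumsum((codes > 3).astype(np.int64))])
    valid = (bad[k:] - bad[:-k]) == 0
    return ids[valid]


def _decode_ids(ids: np.ndarray, k: int) -> np.ndarray:
    out = np.empty((ids.size, k), dtype=np.int64)
    rem = ids.copy()
    for j in range(k - 1, -1, -1):
        out[:, j] = rem % 4
        rem //= 4
    return out


def _hamming1(a: str, b: str) -> bool:
    return len(a) == len(b) and sum(x != y for x, y in zip(a, b)) <= 1


def kmer_enrichment_scan(
    foreground: Sequence[str],
    background_model: MarkovBackground,
    lengths: Sequence[int] = tuple(range(6, 16)),
    top_n: int = 5,
    min_count: int = 3,
) -> pd.DataFrame:
    """Rank k-mers by enrichment over a Markov background.

    For each length, every k-mer observed at least ``min_count`` times in
    the foreground is scored by the Poisson likelihood-ratio statistic

        G = 2 * (obs * ln(obs / exp) - (obs - exp)),

    where the expected count is n_positions * P(k-mer) under the
    background model.  G weighs the observed support as well as the fold
    enrichment, so a well-supported planted motif outranks rare long
    k-mers whose raw fold enrichment is inflated by a tiny expectation
    (the raw log fold is reported alongside).  K-mers that are substrings
    of, contain, or are single-mismatch neighbors of a higher-scoring
    k-mer are greedily collapsed; the ``top_n`` survivors per length are
    returned, ranked by score.
    """
    if not foreground:
        raise ValueError("empty foreground")
    coded = [encode(s) for s in foreground]
    candidates: List[dict] = []
    for k in lengths:
        all_ids = [
            ids for c in coded if (ids := _kmer_ids(c, k)).size
        ]
        if not all_ids:
            continue
        ids = np.concatenate(all_ids)
        n_pos = ids.size
        uniq, counts = np.unique(ids, return_counts=True)
        keep = counts >= min_count
        uniq, counts = uniq[keep], counts[keep]
        if uniq.size == 0:
            continue
        codes = _decode_ids(uniq, k)
        logp = background_model.kmer_logp(codes)
        expected = n_pos * np.exp(logp)
        log_fold = np.log(counts / expected)
        gscore = 2.0 * (counts * log_fold - (counts - expected))
        for u, c, e, lf, sc in zip(uniq, counts, expected, log_fold, gscore):
            if sc <= 0 or lf <= 0:
                continue
            kmer = "".join(_BASES[i] for i in _decode_ids(np.array([u]), k)[0])
            candidates.append(
                {"kmer": kmer, "length": k, "observed": int(c),
                 "expected": float(e), "log_fold": float(lf),
                 "score": float(sc)}
            )
    candidates.sort(key=lambda d: d["score"], reverse=True)
    accepted: List[dict] = []
    per_length: Dict[int, int] = {}
    for cand in candidates:
        redundant = False
        for acc in accepted:
            a, b = cand["kmer"], acc["kmer"]
            if a in b or b in a or _hamming1(a, b):
                redundant = True
                break
        if redundant:
            continue
        if per_length.get(cand["length"], 0) >= top_n:
            continue
        accepted.append(cand)
        per_length[cand["length"]] = per_length.get(cand["length"], 0) + 1
    df = pd.DataFrame(accepted)
    if not df.empty:
        df.insert(0, "rank", range(1, len(df) + 1))
    return df


def collect_instances(
    foreground: Sequence[str], kmer: str, max_mismatch: int = 1
) -> List[str]:
    """Gather aligned occurrences of a k-mer (within max_mismatch) from
    the foreground, to seed PSSM construction."""
    k = len(kmer)
    target = encode(kmer)
    out: List[str] = []
    for seq in foreground:
        codes = encode(seq)
        if codes.size < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        ok = ~np.any(windows > 3, axis=1)
        mism = np.sum(windows != target[None, :], axis=1)
        for i in np.nonzero(ok & (mism <= max_mismatch))[0]:
            out.append(seq[i : i + k].upper())
    return out


# ---------------------------------------------------------------------------
# feature assembly and classification
# ---------------------------------------------------------------------------

@dataclass
class SiteFeatures:
    """Per-site feature record for classification."""

    site: GenomicInterval | None
    motif1_max: float
    motif2_max: float
    cpg_density: float
    label: str | None = None
    truncated: bool = False


def extract_features(
    sites: Sequence[GenomicInterval],
    genome: GenomeSequence,
    pssm1: PSSM,
    pssm2: PSSM,
    region: int = 500,
    labels: Sequence[str] | None = None,
) -> List[SiteFeatures]:
    """Compute the three sequence features on the central region of each
    site (default 500 bp centered on the peak center; truncated and
    flagged at chromosome ends)."""
    half = region // 2
    out: List[SiteFeatures] = []
    for i, site in enumerate(sites):
        if site.chrom not in genome:
            raise ValueError(f"chromosome {site.chrom!r} missing from genome")
        seq = genome[site.chrom]
        c = site.center
        lo, hi = max(0, c - half), min(len(seq), c + half)
        window = seq[lo:hi]
        out.append(
            SiteFeatures(
                site=site,
                motif1_max=max_pssm_score(window, pssm1),
                motif2_max=max_pssm_score(window, pssm2),
                cpg_density=cpg_density(window),
                label=labels[i] if labels is not None else None,
                truncated=(hi - lo) < region,
            )
        )
    return out


def features_to_arrays(
    features: Sequence[SiteFeatures],
) -> Tuple[np.ndarray, np.ndarray]:
    X = np.array(
        [[f.motif1_max, f.motif2_max, f.cpg_density] for f in features]
    )
    y = np.array([f.label for f in features])
    return X, y


def crossval_classifier(
    features: Sequence[SiteFeatures],
    folds: int = 10,
    kernel: str = "rbf",
    C: float = 1.0,
    seed: int = 0,
):
    """Stratified k-fold cross-validation of an SVM on the 3 features.

    Features are standardized using training-fold statistics only.
    Returns (mean accuracy, per-fold accuracies, pipeline fitted on the
    full data for decision-boundary export).
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X, y = features_to_arrays(features)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need both classes present")
    if X.shape[0] < folds:
        raise ValueError("fewer samples than folds")
    model = make_pipeline(StandardScaler(), SVC(kernel=kernel, C=C))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = cross_val_score(model, X, y, cv=cv, scoring="accuracy")
    model.fit(X, y)
    return float(fold_acc.mean()), fold_acc, model
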