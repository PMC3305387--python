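"""Skellam null model: pmf/tail oracles, scanning, merging, adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from skelldiff.genomic_io import GenomicInterval
from skelldiff.normalization import NormalizationResult
from skelldiff.skellam_diff import (
    AdjustmentParams,
    adjust_pvalue,
    call_differential,
    estimate_correlation_length,
    merge_significant_windows,
    scan_windows,
    skellam_pmf,
    skellam_tail_pvalue,
    window_counts,
)

from conftest import make_reads, skellam_pmf_oracle, skellam_tail_oracle


def unit_norm(scale=1.0):
    qs = np.linspace(0.01, 1.0, 100)
    return NormalizationResult(qs, np.full(100, scale), 1.0, scale,
                               0.0, scale, 0.0, 100)


class TestPmf:
    def test_matches_convolution_oracle(self):
        for mu1, mu2 in [(1, 1), (2, 0.5), (10, 3), (0.1, 7), (20, 20)]:
            for k in (-15, -3, 0, 2, 8, 30):
                assert skellam_pmf(k, mu1, mu2) == pytest.approx(
                    skellam_pmf_oracle(k, mu1, mu2), abs=1e-13
                )

    def test_matches_scipy(self):
        ks = np.arange(-40, 41)
        mine = np.array([skellam_pmf(k, 6.5, 2.3) for k in ks])
        assert np.allclose(mine, stats.skellam.pmf(ks, 6.5, 2.3), atol=1e-14)

    def test_degenerate_reduces_to_poisson(self):
        assert skellam_pmf(3, 2, 0) == pytest.approx(stats.poisson.pmf(3, 2))
        assert skellam_pmf(-1, 2, 0) == 0.0
        assert skellam_pmf(-3, 0, 2) == pytest.approx(stats.poisson.pmf(3, 2))

    def test_known_value(self):
        # e^-2 I0(2)
        assert skellam_pmf(0, 1, 1) == pytest.approx(0.308508322553671, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mu=st.floats(0.05, 20), k=st.integers(-30, 30)
    )
    def test_symmetry_at_equal_means(self, mu, k):
        assert skellam_pmf(k, mu, mu) == pytest.approx(
            skellam_pmf(-k, mu, mu), rel=1e-12
        )

    def test_sums_to_one(self):
        ks = np.arange(-200, 201)
        for mu1, mu2 in [(20, 20), (5, 15), (0.5, 0.5)]:
            total = sum(skellam_pmf(int(k), mu1, mu2) for k in ks)
            assert abs(total - 1.0) < 1e-10

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            skellam_pmf(0, -1, 1)
        with pytest.raises(ValueError):
            skellam_pmf(0, 0, 0)


class TestTail:
    def test_central_value(self):
        # P(D <= 0 | mu, mu) = (1 + pmf(0)) / 2 by symmetry
        p = skellam_tail_pvalue(0, 1, 1, "less")
        assert p == pytest.approx((1 + skellam_pmf(0, 1, 1)) / 2, abs=1e-13)

    @pytest.mark.parametrize(
        "d,mu1,mu2,alt",
        [(-10, 1, 1, "less"), (0, 1, 1, "less"), (5, 3, 7, "greater"),
         (90, 55, 55, "greater"), (-3, 0.5, 8, "less"), (12, 9, 2, "greater")],
    )
    def test_matches_convolution_oracle(self, d, mu1, mu2, alt):
        assert skellam_tail_pvalue(d, mu1, mu2, alt) == pytest.approx(
            skellam_tail_oracle(d, mu1, mu2, alt), rel=1e-10, abs=1e-15
        )

    def test_monotone_in_observed_difference(self):
        ps = [skellam_tail_pvalue(d, 4, 4, "less") for d in range(-20, 21)]
        assert all(p1 <= p2 for p1, p2 in zip(ps, ps[1:]))
        pg = [skellam_tail_pvalue(d, 4, 4, "greater") for d in range(-20, 21)]
        assert all(p1 >= p2 for p1, p2 in zip(pg, pg[1:]))

    def test_two_tails_cover_distribution(self):
        # P(D <= d) + P(D >= d+1) = 1
        for d in (-5, 0, 7):
            s = skellam_tail_pvalue(d, 6, 3, "less") + skellam_tail_pvalue(
                d + 1, 6, 3, "greater"
            )
            assert s == pytest.approx(1.0, abs=1e-12)


class TestScan:
    def test_no_reads_no_calls(self):
        genome = {"chr1": 100_000}
        a = make_reads({"chr1": []}, genome, "a")
        b = make_reads({"chr1": []}, genome, "b")
        calls = scan_windows(a, b, unit_norm(), AdjustmentParams(L=1e5))
        assert calls == []

    def test_window_counts_slide(self):
        pos = np.array([0, 150, 399, 400])
        wc = window_counts(pos, 1200, 400, 100)
        assert wc[0] == 3       # [0, 400)
        assert wc[1] == 3       # [100, 500): 150, 399, 400
        assert wc[4] == 1       # [400, 800)

    def test_planted_depletion_called_loss(self):
        genome = {"chr1": 100_000}
        rng = np.random.default_rng(0)
        peak = rng.integers(50_000, 50_400, 100)
        bg_a = rng.integers(0, 100_000, 500)
        bg_b = rng.integers(0, 100_000, 500)
        a = make_reads({"chr1": np.concatenate([bg_a, peak])}, genome, "a")
        b = make_reads({"chr1": bg_b}, genome, "b")
        params = AdjustmentParams(L=1e5)
        calls = scan_windows(a, b, unit_norm(), params, significant_only=True)
        assert calls, "expected significant windows over the planted peak"
        assert all(c.direction == "loss" for c in calls)
        assert min(c.p_skellam for c in calls) < 1e-7
        covering = [c for c in calls
                    if c.interval.start <= 50_200 < c.interval.end]
        assert covering

    def test_window_must_be_multiple_of_step(self):
        with pytest.raises(ValueError):
            AdjustmentParams(L=1e6, window=400, step=300)


class TestMerge:
    def test_overlapping_windows_union(self):
        from skelldiff.skellam_diff import DifferentialCall

        genome = {"chr1": 10_000}
        a = make_reads({"chr1": np.arange(0, 600, 10)}, genome, "a")
        b = make_reads({"chr1": []}, genome, "b")
        wins = [
            DifferentialCall(GenomicInterval("chr1", 0, 400), 40, 0, "loss",
                             1e-9, -9.0),
            DifferentialCall(GenomicInterval("chr1", 200, 600), 40, 0, "loss",
                             1e-9, -9.0),
        ]
        peaks = merge_significant_windows(wins, a, b, unit_norm(),
                                          AdjustmentParams(L=1e4))
        assert len(peaks) == 1
        assert (peaks[0].interval.start, peaks[0].interval.end) == (0, 600)
        assert peaks[0].merged_from == 2

    def test_distant_windows_stay_separate(self):
        from skelldiff.skellam_diff import DifferentialCall

        genome = {"chr1": 10_000}
        a = make_reads({"chr1": np.concatenate([np.arange(0, 400, 10),
                                                np.arange(800, 1200, 10)])},
                       genome, "a")
        b = make_reads({"chr1": []}, genome, "b")
        wins = [
            DifferentialCall(GenomicInterval("chr1", 0, 400), 40, 0, "loss",
                             1e-9, -9.0),
            DifferentialCall(GenomicInterval("chr1", 800, 1200), 40, 0, "loss",
                             1e-9, -9.0),
        ]
        peaks = merge_significant_windows(wins, a, b, unit_norm(),
                                          AdjustmentParams(L=1e4))
        assert len(peaks) == 2

    def test_merged_p_recomputed_and_stronger(self):
        from skelldiff.skellam_diff import DifferentialCall

        genome = {"chr1": 10_000}
        # adjacent windows each (30, 0): merged peak has (60, 0)
        a = make_reads({"chr1": np.concatenate([
            np.linspace(0, 399, 30).astype(int),
            np.linspace(400, 799, 30).astype(int)])}, genome, "a")
        b = make_reads({"chr1": []}, genome, "b")
        p_single = skellam_tail_pvalue(30, 15.0, 15.0, "greater")
        wins = [
            DifferentialCall(GenomicInterval("chr1", 0, 400), 30, 0, "loss",
                             p_single, float(np.log10(p_single))),
            DifferentialCall(GenomicInterval("chr1", 400, 800), 30, 0, "loss",
                             p_single, float(np.log10(p_single))),
        ]
        peaks = merge_significant_windows(wins, a, b, unit_norm(),
                                          AdjustmentParams(L=1e4))
        assert len(peaks) == 1
        assert peaks[0].count_a == 60 and peaks[0].count_b == 0
        oracle = skellam_tail_oracle(60, 30.0, 30.0, "greater")
        assert peaks[0].p_skellam == pytest.approx(oracle, rel=1e-9)
        assert peaks[0].p_skellam < p_single


class TestCorrelationLength:
    def test_isolated_significant_windows(self):
        track = np.array([1, 1e-9, 1, 1e-9, 1, 1])
        assert estimate_correlation_length(track, 1e-7) == 1.0

    def test_uniform_runs(self):
        track = np.array([1e-9] * 5 + [1.0] * 3 + [1e-9] * 5)
        assert estimate_correlation_length(track, 1e-7) == 5.0

    def test_mixed_runs_mean(self):
        track = np.concatenate([
            np.full(3, 1e-9), [1.0], np.full(5, 1e-9), [1.0], np.full(7, 1e-9)
        ])
        assert estimate_correlation_length(track, 1e-7) == 5.0

    def test_no_significant_degenerate_default(self):
        assert estimate_correlation_length(np.ones(100), 1e-7) == 1.0

    def test_runs_do_not_span_chromosomes(self):
        tracks = [np.full(3, 1e-9), np.full(3, 1e-9)]
        assert estimate_correlation_length(tracks, 1e-7) == 3.0


class TestAdjust:
    def test_fixed_points_and_known_value(self):
        params = AdjustmentParams(L=2.6e9, EC=5000)
        assert adjust_pvalue(0.0, params) == 0.0
        assert adjust_pvalue(9.86e-8, params) == pytest.approx(0.050, abs=5e-4)

    def test_inverts_printed_relation(self):
        params = AdjustmentParams(L=1e9, EC=42)
        for p in (1e-12, 1e-8, 1e-6):
            adj = adjust_pvalue(p, params)
            back = -np.log1p(-adj) * params.EC / params.L
            assert back == pytest.approx(p, rel=1e-10)

    def test_strictly_monotone_until_float_saturation(self):
        params = AdjustmentParams(L=1e8, EC=10)
        ps = np.logspace(-12, -8, 30)      # p*L/E[C] stays below 0.1
        adj = adjust_pvalue(ps, params)
        assert np.all(np.diff(adj) > 0)
        # beyond saturation the adjusted p clamps to 1 (never decreases)
        big = adjust_pvalue(np.array([1e-5, 1e-4]), params)
        assert np.all(big == 1.0)

    def test_sidak_first_order_agreement(self):
        # with EC=1, L = m*step: matches 1-(1-p)^m for small p
        m, step = 100_000, 100
        params = AdjustmentParams(L=m * step, EC=1.0, step=step)
        for p in (1e-8, 1e-6, 1e-4 / step):
            sidak = 1 - (1 - p) ** (params.L / params.EC)
            assert adjust_pvalue(p, params) == pytest.approx(sidak, rel=0.01)


class TestCallDifferential:
    def test_identical_pairs_yield_no_calls(self):
        from skelldiff.synthetic_data import simulate_paired_reads

        a, b, _ = simulate_paired_reads(
            {"chr1": 2_000_000}, n_peaks=0, depleted_fraction=0,
            n_reads_a=40_000, seed=3,
        )
        from skelldiff.normalization import normalize_pair

        norm = normalize_pair(a, b, bin_size=10_000)
        peaks, _ = call_differential(a, b, norm, AdjustmentParams(L=2e6))
        assert peaks == []
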