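"""Overlap statistics: center matching, Fisher exactness, profiles."""

import numpy as np
import pytest
from scipy import stats

from skelldiff.genomic_io import GenomicInterval
from skelldiff.interval_stats import (
    aggregate_profile,
    centers_within,
    cutoff_sensitivity,
    depletion_score,
    fisher_overlap_test,
    fisher_two_sided,
    fraction_overlapping,
    nearest_distance_transform,
)

from conftest import fisher_enum_oracle, make_reads, skellam_tail_oracle


def peak(chrom, center, half=200):
    return GenomicInterval(chrom, center - half, center + half)


class TestCentersWithin:
    def test_inclusive_threshold_boundary(self):
        a = [GenomicInterval("chr1", 0, 2000)]       # center 1000
        near = [GenomicInterval("chr1", 2000, 3999)]  # center 2999
        far = [GenomicInterval("chr1", 2002, 4001)]   # center 3001
        assert centers_within(a, near, 2000)[0][0]
        assert not centers_within(a, far, 2000)[0][0]

    def test_identical_sets_all_match(self):
        peaks = [peak("chr1", c) for c in (1000, 5000, 9000)]
        flags, pairs = centers_within(peaks, peaks, 2000)
        assert flags.all()
        assert pairs == [(0, 0), (1, 1), (2, 2)]

    def test_match_relation_symmetric(self):
        rng = np.random.default_rng(0)
        a = [peak("chr1", int(c)) for c in np.sort(rng.integers(500, 99_500, 30))]
        b = [peak("chr1", int(c)) for c in np.sort(rng.integers(500, 99_500, 25))]
        fa, _ = centers_within(a, b, 2000)
        fb, _ = centers_within(b, a, 2000)
        assert fa.any() == fb.any()
        # any matched a-peak implies some b-peak matches back and vice versa
        assert fa.sum() > 0 and fb.sum() > 0

    def test_different_chromosomes_never_match(self):
        a = [peak("chr1", 1000)]
        b = [peak("chr2", 1000)]
        assert not centers_within(a, b, 2000)[0][0]


class TestFisher:
    def test_spec_tables_against_enumeration(self):
        assert fisher_two_sided(3, 1, 1, 3) == pytest.approx(34 / 70, abs=1e-12)
        assert fisher_two_sided(0, 5, 5, 0) == pytest.approx(2 / 252, abs=1e-12)
        assert fisher_two_sided(2, 2, 2, 2) == pytest.approx(1.0, abs=1e-12)

    def test_matches_rational_enumeration_small_universe(self):
        for n in range(2, 16):
            for r in range(n + 1):
                for c in range(n + 1):
                    for a in range(max(0, r + c - n), min(r, c) + 1):
                        args = (a, r - a, c - a, n - r - c + a)
                        assert fisher_two_sided(*args) == pytest.approx(
                            fisher_enum_oracle(*args), abs=1e-12
                        )

    def test_cross_check_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 12, 4)
            if min(t[0] + t[1], t[2] + t[3], t[0] + t[2], t[1] + t[3]) == 0:
                continue
            sp = stats.fisher_exact([[t[0], t[1]], [t[2], t[3]]])[1]
            assert fisher_two_sided(*t) == pytest.approx(sp, rel=1e-9)

    def test_flag_vector_tally_and_odds(self):
        a = [True] * 4 + [False] * 4
        b = [True, True, True, False, True, False, False, False]
        res = fisher_overlap_test(a, b)
        assert (res.both, res.a_only, res.b_only, res.neither) == (3, 1, 1, 3)
        assert res.odds_ratio == pytest.approx(9.0)
        assert res.universe_size == 8

    def test_degenerate_margin(self):
        res = fisher_overlap_test([False] * 6, [True, False] * 3)
        assert res.p_two_sided == 1.0 and res.degenerate
        assert np.isnan(res.odds_ratio)

    def test_infinite_odds_ratio(self):
        res = fisher_overlap_test([True] * 3 + [False] * 3,
                                  [True] * 3 + [False] * 3)
        assert res.odds_ratio == float("inf")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap_test([True], [True, False])


class TestDepletionScore:
    def test_zero_counts_zero_score(self):
        assert depletion_score(0, 0) == 0.0

    def test_definition_is_minus_log10_p(self):
        score = depletion_score(100, 10, scale=1.0)
        mu = 55.0
        oracle = skellam_tail_oracle(90, mu, mu, "greater")
        assert score == pytest.approx(-np.log10(oracle), abs=1e-6)

    def test_stronger_depletion_scores_higher(self):
        assert depletion_score(100, 5) > depletion_score(100, 50) > \
            depletion_score(50, 50)

    def test_survives_pvalue_underflow(self):
        # p far below float minimum still yields a finite score
        score = depletion_score(5000, 0)
        assert np.isfinite(score) and score > 400


class TestCutoffSensitivity:
    def _peaks(self, centers, chrom="chr1"):
        return [peak(chrom, c) for c in centers]

    def test_identical_sets_full_overlap(self):
        cuts = [10.0 ** -e for e in range(7, 13)]
        sets = {c: self._peaks([1000, 5000, 9000]) for c in cuts}
        mat = cutoff_sensitivity(sets, sets)
        assert np.allclose(mat.to_numpy(), 100.0)

    def test_disjoint_chromosomes_zero(self):
        cuts = [1e-7, 1e-8]
        a = {c: self._peaks([1000], "chr1") for c in cuts}
        b = {c: self._peaks([1000], "chr2") for c in cuts}
        assert np.allclose(cutoff_sensitivity(a, b).to_numpy(), 0.0)

    def test_nested_sets_nonincreasing_with_stricter_cutoff(self):
        cuts = [1e-7, 1e-8, 1e-9]
        centers = [1000, 20_000, 40_000, 60_000]
        b = {1e-7: self._peaks(centers),
             1e-8: self._peaks(centers[:3]),
             1e-9: self._peaks(centers[:1])}
        a = {c: self._peaks(centers) for c in cuts}
        mat = cutoff_sensitivity(a, b).to_numpy()
        for row in mat:
            assert all(x >= y - 1e-9 for x, y in zip(row, row[1:]))

    def test_empty_a_set_missing_not_zero(self):
        a = {1e-7: [], 1e-8: self._peaks([1000])}
        b = {1e-7: self._peaks([1000]), 1e-8: self._peaks([1000])}
        mat = cutoff_sensitivity(a, b)
        assert np.isnan(mat.loc[1e-7]).all()
        assert (mat.loc[1e-8] == 100.0).all()


class TestAggregateProfile:
    def test_reads_at_centers_fill_central_column(self):
        genome = {"chr1": 100_000}
        anchors = [peak("chr1", c) for c in (20_000, 50_000, 80_000)]
        reads = make_reads({"chr1": [20_000, 50_000, 80_000]}, genome)
        prof = aggregate_profile(reads, anchors, flank=5000, bin_size=100)
        center_col = 5000 // 100
        assert prof.values[:, center_col].sum() == 3
        assert prof.values.sum() == 3

    def test_total_equals_reads_within_flank(self):
        rng = np.random.default_rng(2)
        genome = {"chr1": 200_000}
        pos = rng.integers(0, 200_000, 5000)
        anchors = [peak("chr1", 100_000)]
        reads = make_reads({"chr1": pos}, genome)
        prof = aggregate_profile(reads, anchors, flank=5000, bin_size=100)
        expected = np.sum((pos >= 95_000) & (pos < 105_000))
        assert prof.values.sum() == expected

    def test_uniform_reads_flat_columns(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": 1_000_000}
        pos = rng.integers(0, 1_000_000, 200_000)
        anchors = [peak("chr1", int(c))
                   for c in rng.integers(10_000, 990_000, 200)]
        reads = make_reads({"chr1": pos}, genome)
        prof = aggregate_profile(reads, anchors, flank=2000, bin_size=100)
        col_sums = prof.values.sum(axis=0)
        mean = col_sums.mean()
        assert np.all(np.abs(col_sums - mean) < 4 * np.sqrt(mean))

    def test_edge_rows_flagged(self):
        genome = {"chr1": 100_000}
        anchors = [peak("chr1", 1000)]
        reads = make_reads({"chr1": [500]}, genome)
        prof = aggregate_profile(reads, anchors, flank=5000, bin_size=100)
        assert prof.truncated[0]


class TestNearestDistanceTransform:
    def test_signed_log_values(self):
        ref = [peak("chr1", 5000)]
        assert nearest_distance_transform([peak("chr1", 6000)], ref)[0] == \
            pytest.approx(3.0)
        assert nearest_distance_transform([peak("chr1", 4000)], ref)[0] == \
            pytest.approx(-3.0)
        assert nearest_distance_transform([peak("chr1", 5000)], ref)[0] == 0.0

    def test_missing_chromosome_is_nan(self):
        vals = nearest_distance_transform([peak("chr2", 5000)],
                                          [peak("chr1", 5000)])
        assert np.isnan(vals[0])

    def test_antisymmetry_of_exchanged_roles(self):
        s, r = peak("chr1", 8000), peak("chr1", 5000)
        d1 = nearest_distance_transform([s], [r])[0]
        d2 = nearest_distance_transform([r], [s])[0]
        assert d1 == pytest.approx(-d2)


class TestFractionOverlapping:
    def test_full_and_zero_overlap(self):
        peaks = [GenomicInterval("chr1", 100, 200)]
        inside = [GenomicInterval("chr1", 0, 500)]
        away = [GenomicInterval("chr1", 300, 500)]
        assert fraction_overlapping(peaks, inside) == 1.0
        assert fraction_overlapping(peaks, away) == 0.0

    def test_single_bp_overlap_counts(self):
        peaks = [GenomicInterval("chr1", 100, 200)]
        touching = [GenomicInterval("chr1", 199, 300)]
        bookended = [GenomicInterval("chr1", 200, 300)]
        assert fraction_overlapping(peaks, touching) == 1.0
        assert fraction_overlapping(peaks, bookended) == 0.0

    def test_planted_fraction_recovered(self):
        rng = np.random.default_rng(4)
        islands = [GenomicInterval("chr1", int(s), int(s) + 1000)
                   for s in np.arange(0, 4_000_000, 10_000)]
        peaks = []
        for i in range(400):
            if i % 2 == 0:
                isl = islands[int(rng.integers(0, len(islands)))]
                c = int(rng.integers(isl.start + 200, isl.end - 200))
            else:
                c = int(rng.integers(0, 4_000_000))
                while any(abs(c - isl.center) < 1500 for isl in islands[
                        max(0, c // 10_000 - 1): c // 10_000 + 2]):
                    c = int(rng.integers(0, 4_000_000))
            peaks.append(peak("chr1", c, half=150))
        frac = fraction_overlapping(peaks, islands)
        assert abs(frac - 0.5) < 0.05

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fraction_overlapping([], [GenomicInterval("chr1", 0, 10)])
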