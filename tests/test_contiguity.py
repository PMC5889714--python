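"""Repeat-bridging model: exact examples, Monte-Carlo oracle, monotonicity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contigprophet.contiguity import (
    ReadLengthDistribution,
    RepeatHistogram,
    RepeatInterval,
    RepeatTrack,
    build_repeat_track,
    contiguity_curve,
    expected_ng50,
    prob_any_unbridged,
    prob_repeat_unbridged,
    repeat_length_histogram,
    spanned_repeat_length,
)


def mc_unbridged_fraction(rng, genome_size, lengths, repeat_starts, repeat_length,
                          trials=100_000):
    """Uniform-placement bridging oracle, independent of the analytic formula.

    Reads start uniformly over the genome (truncated at the end); a repeat
    is bridged when some read covers it plus one base of flank on each
    side. Returns per-repeat unbridged fractions and the any-unbridged
    fraction over trials.
    """
    per_repeat = np.ones((len(repeat_starts), trials), dtype=bool)
    for L in lengths:
        starts = rng.integers(0, genome_size, trials)
        ends = np.minimum(starts + L, genome_size)
        for k, s in enumerate(repeat_starts):
            e = s + repeat_length
            bridges = (starts <= s - 1) & (ends >= e + 1)
            per_repeat[k] &= ~bridges
    return per_repeat.mean(axis=1), per_repeat.any(axis=0).mean()


class TestProbRepeatUnbridged:
    def test_no_read_long_enough(self):
        dist = ReadLengthDistribution([100, 102], 10_000)
        assert prob_repeat_unbridged(100, dist) == 1.0

    def test_single_placement_window(self):
        # one read of L = ell + 3: exactly one admissible start position
        dist = ReadLengthDistribution([103], 10_000)
        assert prob_repeat_unbridged(100, dist) == pytest.approx(1 - 1 / 10_000)

    def test_monte_carlo_oracle_single_repeat(self, rng):
        G = 200_000
        lengths = rng.integers(1_000, 9_000, 150)
        dist = ReadLengthDistribution(lengths, G)
        ell = 2_000
        p = prob_repeat_unbridged(ell, dist)
        frac, _ = mc_unbridged_fraction(rng, G, lengths, [90_000], ell)
        mc = frac[0]
        se = math.sqrt(max(mc * (1 - mc), 1e-9) / 100_000)
        assert abs(p - mc) <= 3 * se + 1e-9

    def test_monotone_in_repeat_length_and_reads(self, rng):
        G = 500_000
        lengths = list(rng.integers(2_000, 20_000, 200))
        dist = ReadLengthDistribution(lengths, G)
        ps = [prob_repeat_unbridged(ell, dist) for ell in range(1_000, 25_000, 1_000)]
        assert all(0.0 <= p <= 1.0 for p in ps)
        assert all(a <= b + 1e-12 for a, b in zip(ps, ps[1:]))
        more = ReadLengthDistribution(lengths + [15_000] * 20, G)
        assert prob_repeat_unbridged(5_000, more) <= prob_repeat_unbridged(5_000, dist)

    def test_exponential_approximation_close_when_windows_small(self, rng):
        G = 50_000_000
        dist = ReadLengthDistribution(rng.integers(5_000, 30_000, 500), G)
        exact = prob_repeat_unbridged(2_000, dist)
        approx = prob_repeat_unbridged(2_000, dist, approximate=True)
        assert abs(exact - approx) < 1e-3

    def test_fixed_length_reduces_to_classical_form(self):
        # all reads one length L: p = (1 - (L-ell-2)/G)^N ~ exp(-N(L-ell-2)/G)
        G, L, N, ell = 1_000_000, 10_000, 300, 4_000
        dist = ReadLengthDistribution([L] * N, G)
        assert prob_repeat_unbridged(ell, dist) == pytest.approx(
            (1 - (L - ell - 2) / G) ** N
        )


class TestProbAnyUnbridged:
    def test_zero_and_single_repeat_bins(self):
        dist = ReadLengthDistribution([5_000] * 50, 100_000)
        hist = RepeatHistogram(1000, {2: 1})
        assert prob_any_unbridged(3_000, hist, dist) == 0.0  # empty bin
        p = prob_repeat_unbridged(2_000, dist)
        assert prob_any_unbridged(2_000, hist, dist) == pytest.approx(p)

    def test_five_repeats_closed_form_and_oracle(self, rng):
        G = 150_000
        lengths = rng.integers(2_000, 6_000, 80)
        dist = ReadLengthDistribution(lengths, G)
        ell = 1_000
        hist = RepeatHistogram(1000, {1: 5})
        p = prob_repeat_unbridged(ell, dist)
        P = prob_any_unbridged(ell, hist, dist)
        assert P == pytest.approx(1 - (1 - p) ** 5)
        starts = [10_000, 40_000, 70_000, 100_000, 130_000]
        _, mc_any = mc_unbridged_fraction(rng, G, lengths, starts, ell)
        se = math.sqrt(max(mc_any * (1 - mc_any), 1e-9) / 100_000)
        assert abs(P - mc_any) <= 3 * se + 0.003

    def test_cumulative_aggregation_counts_longer_bins(self):
        dist = ReadLengthDistribution([50_000] * 30, 1_000_000)
        hist = RepeatHistogram(1000, {1: 2, 5: 3, 10: 1})
        p = prob_repeat_unbridged(1_000, dist)
        P = prob_any_unbridged(1_000, hist, dist, cumulative=True)
        assert P == pytest.approx(1 - (1 - p) ** 6)


class TestBuildRepeatTrack:
    SIZES = {"chr1": 10_000}

    def test_zero_threshold_only_merges(self):
        raw = [
            RepeatInterval("chr1", 100, 200, 10.0),
            RepeatInterval("chr1", 150, 300, 95.0),
            RepeatInterval("chr1", 500, 600, 0.0),
        ]
        track = build_repeat_track(raw, 0.0, self.SIZES)
        assert [(iv.start, iv.end) for iv in track.intervals] == [(100, 300), (500, 600)]

    def test_filter_keeps_gaps(self):
        raw = [
            RepeatInterval("chr1", 100, 200, 90.0),
            RepeatInterval("chr1", 400, 500, 0.0, kind="gap"),
        ]
        track = build_repeat_track(raw, 99.0, self.SIZES)
        assert len(track.intervals) == 1
        assert track.intervals[0].kind == "gap"

    def test_abutting_intervals_merge(self):
        raw = [RepeatInterval("chr1", 0, 100, 99.0), RepeatInterval("chr1", 100, 250, 99.0)]
        track = build_repeat_track(raw, 0.0, self.SIZES)
        assert [(iv.start, iv.end) for iv in track.intervals] == [(0, 250)]

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError, match="beyond chromosome"):
            build_repeat_track([RepeatInterval("chr1", 0, 20_000, 99.0)], 0.0, self.SIZES)


class TestRepeatLengthHistogram:
    def test_example_bins(self):
        track = RepeatTrack(
            [
                RepeatInterval("chr1", 0, 500, 99.0),
                RepeatInterval("chr1", 1000, 2500, 99.0),
                RepeatInterval("chr1", 3000, 4500, 99.0),
            ],
            {"chr1": 10_000},
        )
        hist = repeat_length_histogram(track, 1000)
        assert hist.counts == {1: 1, 2: 2}

    def test_empty_track(self):
        hist = repeat_length_histogram(RepeatTrack([], {"chr1": 100}), 1000)
        assert hist.counts == {} and hist.total == 0

    @given(st.lists(st.integers(1, 9_999), max_size=40), st.integers(1, 3_000))
    @settings(max_examples=50, deadline=None)
    def test_total_preserved(self, lengths, bin_width):
        intervals = [
            RepeatInterval("chr1", 10_000 * i, 10_000 * i + ln, 99.0)
            for i, ln in enumerate(lengths)
        ]
        track = RepeatTrack(intervals, {"chr1": 10_000 * (len(lengths) + 1)})
        hist = repeat_length_histogram(track, bin_width)
        assert hist.total == len(intervals)
        # brute-force recount per bin
        for i, count in hist.counts.items():
            assert count == sum(
                1 for ln in lengths if (i - 1) * bin_width < ln <= i * bin_width
            )


class TestSpannedRepeatLength:
    def test_empty_histogram_is_never_exceeded(self):
        dist = ReadLengthDistribution([5_000] * 10, 100_000)
        assert spanned_repeat_length(dist, RepeatHistogram(1000, {})) is None

    def test_vanishing_coverage_returns_first_bin(self):
        dist = ReadLengthDistribution([500], 1_000_000)  # nearly no coverage
        hist = RepeatHistogram(1000, {i: 1 for i in range(1, 101)})
        assert spanned_repeat_length(dist, hist) == 1000

    def test_constant_read_length_cliff(self):
        # reads of 12,002 bridge repeats up to 12,000 when coverage is deep
        G = 3_000_000
        n = int(60 * G / 12_002)  # 60-fold coverage
        dist = ReadLengthDistribution([12_002] * n, G)
        hist = RepeatHistogram(1000, {i: 1 for i in range(1, 101)})
        assert spanned_repeat_length(dist, hist) == 12_000
        # direct evaluation agrees bin by bin around the cliff
        for ell in (11_000, 12_000):
            P = prob_any_unbridged(ell, hist, dist)
            assert (P > 0.05) == (ell == 12_000)

    def test_invalid_alpha(self):
        dist = ReadLengthDistribution([5_000], 100_000)
        with pytest.raises(ValueError):
            spanned_repeat_length(dist, RepeatHistogram(1000, {}), alpha=1.5)


def brute_force_ng50(segment_lengths, genome_size):
    total = 0
    for ln in sorted(segment_lengths, reverse=True):
        total += ln
        if total >= genome_size / 2:
            return ln
    return 0


class TestExpectedNg50:
    def test_no_repeats_full_chromosome(self):
        track = RepeatTrack([], {"chr1": 10_000_000})
        assert expected_ng50(track, 0, 10_000_000) == 10_000_000

    def test_centered_repeat_splits_in_half(self):
        iv = RepeatInterval("chr1", 4_995_000, 5_005_000, 99.0)
        track = RepeatTrack([iv], {"chr1": 10_000_000})
        assert expected_ng50(track, 5_000, 10_000_000) == 4_995_000
        # a 10-kb repeat counted resolvable leaves the chromosome whole
        assert expected_ng50(track, 10_000, 10_000_000) == 10_000_000

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 30))
            intervals = []
            pos = 0
            for _ in range(n):
                pos += int(rng.integers(1_000, 50_000))
                ln = int(rng.integers(500, 20_000))
                intervals.append(RepeatInterval("chr1", pos, pos + ln, 99.0))
                pos += ln
            size = pos + int(rng.integers(1_000, 50_000))
            track = RepeatTrack(intervals, {"chr1": size})
            resolvable = int(rng.integers(0, 25_000))
            segments = []
            cursor = 0
            for iv in intervals:
                if iv.length > resolvable:
                    if iv.start > cursor:
                        segments.append(iv.start - cursor)
                    cursor = iv.end
            if size > cursor:
                segments.append(size - cursor)
            assert expected_ng50(track, resolvable, size) == brute_force_ng50(segments, size)

    def test_monotone_in_resolvable_length(self, small_genome):
        track = small_genome.truth_track
        G = small_genome.total_size
        values = [expected_ng50(track, r, G) for r in range(0, 30_000, 2_000)]
        assert all(a <= b for a, b in zip(values, values[1:]))


class TestContiguityCurve:
    def test_identity_threshold_monotonicity(self, rng):
        intervals = []
        for i in range(30):
            start = 50_000 * i + int(rng.integers(0, 10_000))
            ln = int(rng.integers(2_000, 30_000))
            ident = float(rng.choice([85.0, 92.0, 97.0, 99.5]))
            intervals.append(RepeatInterval("chr1", start, start + ln, ident))
        sizes = {"chr1": 2_000_000}
        dist = ReadLengthDistribution(rng.integers(3_000, 30_000, 300), 2_000_000)
        curves = contiguity_curve(
            intervals, [0.0, 95.0, 99.0], dist, 2_000_000, sizes, max_length=50_000
        )
        by_thr = {c.identity_threshold: c for c in curves}
        # fewer unresolved repeats (higher threshold) can only raise NG50
        assert np.all(by_thr[95.0].expected_ng50 >= by_thr[0.0].expected_ng50)
        assert np.all(by_thr[99.0].expected_ng50 >= by_thr[95.0].expected_ng50)

    def test_degenerate_single_read_distribution(self):
        dist = ReadLengthDistribution([4_000], 100_000)
        curves = contiguity_curve(
            [RepeatInterval("chr1", 10_000, 12_000, 99.0)],
            [0.0],
            dist,
            100_000,
            {"chr1": 100_000},
            max_length=10_000,
        )
        assert len(curves) == 1
        assert np.all((curves[0].p_unbridged >= 0) & (curves[0].p_unbridged <= 1))
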