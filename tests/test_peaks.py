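"""Sliding-window peak detection, cutoff sweep and permutation FDR."""

import numpy as np
import pytest

from conftest import make_peak, make_track
from minichip.peaks import (Peak, PeakCallerConfig, PeakSet, call_peaks,
                            call_peaks_at_cutoff, merge_fragmented_peaks,
                            permutation_fdr, theoretical_max)


def brute_force_regions(positions, m, cutoff, window=500, min_probes=4,
                        max_gap=200, spacing=100):
    """Oracle: enumerate every window placement on one chromosome.

    A window [w, w+window) is hit when it contains >= min_probes adjacent
    (consecutive, gap <= max_gap) above-cutoff probes; overlapping hit
    windows are merged and each merged span yields a region running between
    its outermost above-cutoff probes.
    """
    positions = np.asarray(positions)
    m = np.asarray(m, dtype=float)
    above = m > cutoff
    hit_windows = []
    for w in range(int(positions.min()) - window, int(positions.max()) + 2):
        inside = np.flatnonzero((positions >= w) & (positions < w + window))
        # longest streak of adjacent above-cutoff probes within the window
        best = streak = 0
        prev = None
        for i in inside:
            if above[i]:
                adjacent = (prev is not None and above[prev]
                            and i == prev + 1
                            and positions[i] - positions[prev] <= max_gap)
                streak = streak + 1 if adjacent else 1
                best = max(best, streak)
            else:
                streak = 0
            prev = i
        if best >= min_probes:
            hit_windows.append((w, w + window))
    if not hit_windows:
        return []
    merged = [list(hit_windows[0])]
    for lo, hi in hit_windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    regions = []
    for lo, hi in merged:
        sel = np.flatnonzero(above & (positions >= lo) & (positions < hi))
        if len(sel):
            regions.append((int(positions[sel[0]]),
                            int(positions[sel[-1]] + spacing), len(sel)))
    return regions


class TestTheoreticalMax:
    def test_max_observed_rule(self):
        m = np.zeros(100)
        m[50] = 3.0
        assert theoretical_max(make_track(m), "max_observed") == 3.0

    def test_mean_plus_6sd_on_standard_normal(self):
        m = np.random.default_rng(0).normal(0, 1, 50_000)
        assert theoretical_max(make_track(m)) == pytest.approx(6.0, abs=0.1)

    def test_constant_track_collapses_to_constant(self):
        assert theoretical_max(make_track(np.full(20, 1.5))) == 1.5

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match="10 probes"):
            theoretical_max(make_track(np.zeros(5)))


class TestCallPeaksAtCutoff:
    @pytest.mark.parametrize("k", range(1, 9))
    def test_run_length_threshold_is_four_probes(self, k):
        # k consecutive above-cutoff probes at 100 bp spacing form a peak
        # iff k >= 4
        m = np.zeros(40)
        m[10:10 + k] = 2.0
        regions = call_peaks_at_cutoff(make_track(m), cutoff=1.0)
        if k >= 4:
            assert len(regions) == 1
            assert regions["n_probes"].iloc[0] == k
        else:
            assert len(regions) == 0

    def test_probes_wider_than_window_not_called(self):
        # 4 above-cutoff probes spaced 200 bp span 600 bp > the 500 bp window
        positions = [0, 200, 400, 600]
        m = [2.0] * 4
        regions = call_peaks_at_cutoff(
            make_track(m, positions=positions), cutoff=1.0)
        assert len(regions) == 0

    def test_distant_runs_stay_separate(self):
        m = np.zeros(60)
        m[10:14] = 2.0
        m[34:38] = 2.0  # 2 kb away: window cannot bridge
        regions = call_peaks_at_cutoff(make_track(m), cutoff=1.0)
        assert len(regions) == 2

    def test_region_bounds_are_outermost_probes_plus_spacing(self):
        m = np.zeros(30)
        m[10:15] = 2.0
        regions = call_peaks_at_cutoff(make_track(m), cutoff=1.0)
        assert regions["start"].iloc[0] == 1000
        assert regions["end"].iloc[0] == 1500

    def test_unsorted_track_rejected(self):
        import pandas as pd
        from minichip.normalize import RatioTrack
        probes = pd.DataFrame({
            "probe_id": ["a", "b"], "chromosome": "chr1",
            "position": [200, 100], "m": [0.0, 0.0], "a": [10.0, 10.0]})
        with pytest.raises(ValueError, match="sorted"):
            RatioTrack("t", "m", "ct", probes, state="averaged")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_window_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 200))
        # irregular spacing incl. adjacency-breaking gaps
        gaps = rng.choice([100, 100, 100, 150, 200, 300, 2000], size=n - 1)
        positions = np.concatenate([[0], np.cumsum(gaps)])
        m = rng.normal(0, 1, n) + np.where(rng.random(n) < 0.2, 2.5, 0.0)
        cutoff = 1.0
        got = call_peaks_at_cutoff(
            make_track(m, positions=positions), cutoff,
            PeakCallerConfig())
        spacing = float(np.median(np.diff(positions)))  # as the caller infers
        expected = brute_force_regions(positions, m, cutoff, spacing=spacing)
        got_tuples = [tuple(r) for r in
                      got[["start", "end", "n_probes"]].itertuples(index=False)]
        assert got_tuples == expected


class TestCallPeaks:
    def test_empty_track_yields_empty_peakset(self):
        track = make_track(np.zeros(0))
        assert len(call_peaks(track)) == 0

    def test_single_strong_spike_is_one_strict_peak(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 0.2, 500)
        m[200:206] += 2.0  # 10x noise sd over 6 probes
        ps = call_peaks(make_track(m), PeakCallerConfig(rng_seed=1))
        strict = ps.strict
        assert len(strict) == 1
        assert strict[0].start <= 20000 and strict[0].end >= 20500

    def test_determinism_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        m = rng.normal(0, 0.3, 800)
        m[100:108] += 2.5
        a = call_peaks(make_track(m), PeakCallerConfig(rng_seed=9))
        b = call_peaks(make_track(m), PeakCallerConfig(rng_seed=9))
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_lowering_cutoff_floor_only_extends_peaks(self):
        rng = np.random.default_rng(3)
        m = rng.normal(0, 0.3, 800)
        m[100:108] += 2.5
        m[400:405] += 1.2
        track = make_track(m)
        high = call_peaks(track, PeakCallerConfig(cutoff_low_pct=30,
                                                  rng_seed=4))
        low = call_peaks(track, PeakCallerConfig(cutoff_low_pct=15,
                                                 rng_seed=4))
        for p in high:
            covering = [q for q in low if q.start <= p.start and
                        q.end >= p.end]
            assert covering, "peak lost when lowering the cutoff floor"
            assert covering[0].score_pct >= p.score_pct

    def test_scores_carry_both_percent_and_log2_threshold(self):
        rng = np.random.default_rng(5)
        m = rng.normal(0, 0.2, 600)
        m[300:306] += 2.0
        ps = call_peaks(make_track(m), PeakCallerConfig(rng_seed=5))
        p = ps.strict[0]
        assert p.score_log2 == pytest.approx(
            p.score_pct / 100.0 * ps.theoretical_max)


class TestPermutationFdr:
    def test_fdr_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(6)
        m = rng.normal(0, 0.5, 2000)
        m[100:110] += 3.0
        track = make_track(m)
        cfg = PeakCallerConfig(rng_seed=6)
        ps = call_peaks(track, cfg)
        fdr = permutation_fdr(track, list(ps), cfg)
        levels = sorted(fdr)
        values = [fdr[l] for l in levels]
        assert all(a >= b for a, b in zip(values[1:], values[:-1])) or \
            all(values[i] >= values[i + 1] for i in range(len(values) - 1))
        # explicitly: higher score level -> smaller-or-equal FDR
        for lo, hi in zip(levels, levels[1:]):
            assert fdr[hi] <= fdr[lo]

    def test_extreme_spike_gets_zero_fdr(self):
        rng = np.random.default_rng(7)
        m = rng.normal(0, 0.2, 2000)
        m[500:508] = 8 * 0.2 * 6  # far beyond anything a permutation makes
        ps = call_peaks(make_track(m), PeakCallerConfig(rng_seed=7))
        top = max(ps, key=lambda p: p.score_pct)
        assert top.fdr == 0.0

    def test_no_observed_peaks_returns_empty(self):
        track = make_track(np.zeros(100))
        assert permutation_fdr(track, [], PeakCallerConfig()) == {}

    def test_null_track_low_score_peaks_near_fdr_one(self):
        rng = np.random.default_rng(8)
        m = rng.normal(0, 0.5, 4000)
        track = make_track(m)
        cfg = PeakCallerConfig(rng_seed=8)
        ps = call_peaks(track, cfg)
        if len(ps):
            lowest = min(ps, key=lambda p: p.score_pct)
            assert lowest.fdr > 0.5


class TestMergeFragmentedPeaks:
    def test_nearby_peaks_merge_into_combined_span(self):
        ps = PeakSet([make_peak(1000, 1400), make_peak(1450, 1800)])
        merged = merge_fragmented_peaks(ps, gap_bp=100)
        assert len(merged) == 1
        assert merged.peaks[0].bound_area == 800

    def test_distant_peaks_unchanged(self):
        ps = PeakSet([make_peak(1000, 1400), make_peak(1900, 2300)])
        merged = merge_fragmented_peaks(ps, gap_bp=100)
        assert len(merged) == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_interval_union_invariants(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(np.arange(0, 40) * 600, 10, replace=False))
        peaks = [make_peak(int(s), int(s + rng.integers(100, 500)))
                 for s in starts]
        ps = PeakSet(peaks)
        merged = merge_fragmented_peaks(ps, gap_bp=int(rng.integers(0, 800)))
        assert len(merged) <= len(ps)
        assert merged.total_bound_bp() >= max(p.bound_area for p in ps)
        # merged intervals cover every original peak
        for p in ps:
            assert any(q.start <= p.start and q.end >= p.end for q in merged)
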