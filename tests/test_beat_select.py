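import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uwave.beat_select import (EmptyHistogramError, compute_rr_histogram,
                               extract_beat_windows, select_qualifying_beats)
from uwave.io_ecg import ECGRecord

from conftest import rr_to_peaks


def brute_force_select(rr_ms, rr_bin=100.0, rr_min=650.0):
    """Independent oracle: exhaustive filter over every beat.

    Beat i (0-based over peaks) qualifies iff its preceding RR falls in the
    modal half-open bin (edges at multiples of rr_bin, first-bin tie-break)
    and its following RR exceeds rr_min.
    """
    rr = np.asarray(rr_ms, dtype=float)
    bins = np.floor(rr / rr_bin).astype(int)
    counts = {}
    for b in bins:
        counts[b] = counts.get(b, 0) + 1
    mode = min(b for b in counts if counts[b] == max(counts.values()))
    lo, hi = mode * rr_bin, (mode + 1) * rr_bin
    chosen = set()
    for i in range(1, len(rr)):
        if lo <= rr[i - 1] < hi and rr[i] > rr_min:
            chosen.add(i)  # beat index: i-th peak has preceding rr[i-1]
    return chosen


class TestRRHistogram:
    def test_four_interval_example(self):
        peaks = rr_to_peaks([700, 710, 720, 850], fs=1000.0)
        h = compute_rr_histogram(peaks, 100.0)
        assert h.counts.sum() == 4
        assert h.mode_interval == (700.0, 800.0)
        assert h.counts[h.mode_bin] == 3
        assert h.counts[-1] == 1  # [800, 900)

    def test_single_interval(self):
        h = compute_rr_histogram(rr_to_peaks([650.0], fs=1000.0))
        assert h.mode_interval == (600.0, 700.0)
        assert h.counts.tolist() == [1]

    def test_tie_breaks_toward_shorter_rr(self):
        rr = [610, 620, 630, 640, 650, 710, 720, 730, 740, 750]
        h = compute_rr_histogram(rr_to_peaks(rr, fs=1000.0))
        assert h.mode_interval == (600.0, 700.0)

    def test_no_usable_intervals_is_error(self):
        peaks = rr_to_peaks([700.0], fs=1000.0)
        peaks.ectopic_flags[:] = True
        with pytest.raises(EmptyHistogramError):
            compute_rr_histogram(peaks)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=300, max_value=1500), min_size=1,
                    max_size=60))
    def test_counts_sum_and_permutation_invariance(self, rr):
        h1 = compute_rr_histogram(rr_to_peaks(rr, fs=1000.0))
        assert h1.counts.sum() == len(rr)
        assert h1.counts[h1.mode_bin] == h1.counts.max()
        rng = np.random.default_rng(0)
        h2 = compute_rr_histogram(
            rr_to_peaks(list(rng.permutation(rr)), fs=1000.0))
        np.testing.assert_array_equal(h1.counts, h2.counts)
        assert h1.mode_interval == h2.mode_interval


class TestSelection:
    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(3, 200)
            rr = rng.uniform(400, 1100, n)
            peaks = rr_to_peaks(rr, fs=500.0)
            hist = compute_rr_histogram(peaks)
            got = select_qualifying_beats(peaks, hist)
            rr_q = np.diff(peaks.indices) / peaks.fs * 1000.0  # as stored
            expect = {peaks.indices[i] for i in brute_force_select(rr_q)}
            assert set(got.r_indices) == expect

    def test_all_equal_rr_every_interior_beat_qualifies(self):
        peaks = rr_to_peaks([800.0] * 20, fs=500.0)
        hist = compute_rr_histogram(peaks)
        got = select_qualifying_beats(peaks, hist)
        np.testing.assert_array_equal(got.r_indices, peaks.indices[1:-1])

    def test_short_following_rr_excludes_all(self):
        peaks = rr_to_peaks([640.0] * 15, fs=500.0)
        hist = compute_rr_histogram(peaks)
        got = select_qualifying_beats(peaks, hist, rr_min=650.0)
        assert len(got) == 0
        assert got.diagnostics["n_failed"]["following_rr"] == 14

    def test_longer_rr_min_selects_subset(self):
        rng = np.random.default_rng(3)
        rr = rng.uniform(500, 1100, 150)
        peaks = rr_to_peaks(rr, fs=500.0)
        hist = compute_rr_histogram(peaks)
        loose = set(select_qualifying_beats(peaks, hist, rr_min=650.0).r_indices)
        tight = set(select_qualifying_beats(peaks, hist, rr_min=800.0).r_indices)
        assert tight <= loose

    def test_ectopic_adjacent_beats_excluded(self):
        peaks = rr_to_peaks([800.0] * 20, fs=500.0)
        peaks.ectopic_flags[7] = True
        hist = compute_rr_histogram(peaks)
        got = select_qualifying_beats(peaks, hist)
        banned = set(peaks.indices[[6, 7, 8]])
        assert not (set(got.r_indices) & banned)


class TestExtractWindows:
    def test_window_sample_arithmetic_at_500hz(self):
        fs = 500.0
        peaks = rr_to_peaks([800.0] * 12, fs=fs)
        n = peaks.n_samples
        x = np.zeros(n)
        x[peaks.indices] = 1000.0  # spike at each R
        rec = ECGRecord(x[np.newaxis], fs, ["V4"])
        hist = compute_rr_histogram(peaks)
        beats = select_qualifying_beats(peaks, hist, window_pre_ms=250.0,
                                        window_post_ms=650.0)
        segs, t = extract_beat_windows(rec, beats)
        assert segs.shape == (len(beats), 451)
        assert t[0] == pytest.approx(-250.0)
        np.testing.assert_allclose(segs[:, 125], 1000.0)  # sample 125 is R
        assert t[125] == 0.0

    def test_single_beat_is_identity_slice(self):
        fs = 500.0
        peaks = rr_to_peaks([800.0, 800.0, 800.0], fs=fs)
        rng = np.random.default_rng(0)
        x = rng.normal(size=peaks.n_samples)
        rec = ECGRecord(x[np.newaxis], fs, ["V4"])
        hist = compute_rr_histogram(peaks)
        beats = select_qualifying_beats(peaks, hist, rr_min=650.0)
        segs, _ = extract_beat_windows(rec, beats)
        r = beats.r_indices[0]
        np.testing.assert_array_equal(
            segs[0], x[r - beats.pre_samples: r + beats.post_samples + 1])
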