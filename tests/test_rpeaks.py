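import numpy as np
import pytest

from uwave.io_ecg import ECGRecord
from uwave.rpeaks import RPeakSeries, detect_r_peaks, flag_ectopics, write_annotations
from uwave.synth import SynthConfig, simulate_record


def gaussian_beat(n, fs, centers, amp=1000.0, width_ms=12.0):
    t = np.arange(n) / fs * 1000.0
    x = np.zeros(n)
    for c in centers:
        x += amp * np.exp(-0.5 * ((t - c * 1000.0 / fs) / width_ms) ** 2)
    return ECGRecord(x[np.newaxis], fs, ["V4"], "unknown", "toy")


class TestDetection:
    def test_af_record_all_beats_found_within_10ms(self, af_record):
        rec, truth = af_record
        peaks = detect_r_peaks(rec)
        assert len(peaks) == len(truth.r_samples)
        tol = int(round(0.010 * rec.fs))
        err = np.abs(peaks.indices - truth.r_samples)
        assert err.max() <= tol

    def test_all_zero_signal_yields_empty_series(self):
        rec = ECGRecord(np.zeros((1, 5000)), 500.0, ["V4"])
        peaks = detect_r_peaks(rec)
        assert len(peaks) == 0

    def test_single_template_beat_at_known_index(self):
        rec = gaussian_beat(5000, 500.0, [2500])
        peaks = detect_r_peaks(rec)
        assert len(peaks) == 1
        assert abs(int(peaks.indices[0]) - 2500) <= 1

    def test_translation_equivariance(self):
        fs = 500.0
        centers = [1000, 1400, 1790, 2230, 2660, 3100]
        rec = gaussian_beat(4200, fs, centers)
        k = 137
        shifted = ECGRecord(
            np.concatenate([np.zeros((1, k)), rec.samples], axis=1),
            fs, ["V4"], "unknown", "toy")
        a = detect_r_peaks(rec).indices
        b = detect_r_peaks(shifted).indices
        assert len(a) == len(b) == len(centers)
        assert np.abs((b - k) - a).max() <= 1  # one-sample tie-break slack


class TestRPeakSeries:
    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            RPeakSeries(np.array([10, 10, 20]), 500.0, 100)

    def test_rr_and_usable_mask(self):
        s = RPeakSeries(np.array([0, 500, 1000, 1500]), 500.0, 2000,
                        ectopic_flags=np.array([False, True, False, False]))
        np.testing.assert_allclose(s.rr_ms, [1000, 1000, 1000])
        # both intervals touching the ectopic beat are dropped
        np.testing.assert_array_equal(s.rr_valid, [False, False, True])
        assert len(s.usable_rr_ms()) == 1


class TestEctopics:
    def test_inserted_premature_wide_beat_flagged(self):
        cfg = SynthConfig(duration_s=120.0, n_ectopics=1, white_sd_uV=5.0,
                          powerline_amp_uV=0.0).sr_defaults()
        rec, truth = simulate_record(cfg, seed=7)
        peaks = detect_r_peaks(rec)
        assert len(peaks) == len(truth.r_samples)
        flagged = flag_ectopics(peaks, rec, mode="SR")
        # the flag set contains the inserted beat
        ect_idx = truth.r_samples[truth.ectopic]
        det_pos = np.argmin(np.abs(peaks.indices - ect_idx[0]))
        assert flagged.ectopic_flags[det_pos]
        # all normal beats away from the ectopic are unflagged
        far = np.abs(peaks.indices[:, None] - ect_idx[None, :]).min(axis=1) > 2 * rec.fs
        assert not flagged.ectopic_flags[far].any()
        # the intervals adjacent to the ectopic contribute no RR
        assert not flagged.rr_valid[det_pos - 1] and not flagged.rr_valid[det_pos]

    def test_clean_record_gets_zero_flags(self, af_record):
        rec, _ = af_record
        peaks = detect_r_peaks(rec)
        assert flag_ectopics(peaks, rec, mode="AF").ectopic_flags.sum() == 0

    def test_af_mode_disables_rr_deviation_rule(self, af_record):
        # AF RR is irregular by nature; with the morphology rule disabled
        # no beat may be flagged
        rec, _ = af_record
        peaks = detect_r_peaks(rec)
        flagged = flag_ectopics(peaks, rec, morph_corr_min=0.0, mode="AF")
        assert flagged.ectopic_flags.sum() == 0

    def test_too_few_peaks_returned_unchanged(self, caplog):
        rec = gaussian_beat(3000, 500.0, [1000, 1800])
        peaks = detect_r_peaks(rec)
        with caplog.at_level("WARNING"):
            out = flag_ectopics(peaks, rec)
        assert out is peaks


def test_annotation_export_text(tmp_path, af_record):
    rec, _ = af_record
    peaks = detect_r_peaks(rec)
    path = tmp_path / "peaks.ann.txt"
    write_annotations(peaks, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "sample\tsymbol"
    assert len(lines) == len(peaks) + 1
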