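"""End-to-end U-wave extraction: detection -> histogram -> selection ->
averaging -> measurement, with one parameter object shared by the CLI and
the study protocols."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import beat_select, rpeaks, umeasure
from .averaging import AverageBeat, compute_average_beat
from .beat_select import (QualifyingBeats, compute_rr_histogram,
                          extract_beat_windows, select_qualifying_beats)
from .io_ecg import ECGRecord, select_lead
from .rpeaks import DetectorParams, detect_r_peaks, flag_ectopics
from .umeasure import UMeasurement

log = logging.getLogger(__name__)


@dataclass
class ExtractParams:
    """All tunables of the extraction pipeline (times in ms, amplitudes in
    uV). Defaults follow the canonical algorithm: 100 ms RR bins, RR_min
    650 ms in AF extended to 800 ms in SR, beat window -250..+650 ms."""

    lead_preference: tuple = ("V4",)
    rr_bin_ms: float = beat_select.RR_BIN_MS
    rr_min_af_ms: float = beat_select.RR_MIN_AF_MS
    rr_min_sr_ms: float = beat_select.RR_MIN_SR_MS
    window_pre_ms: float = beat_select.WINDOW_PRE_MS
    window_post_ms: float = beat_select.WINDOW_POST_MS
    qrs_onset_offset_ms: float = umeasure.QRS_ONSET_OFFSET_MS
    p_onset_offset_ms: float = umeasure.P_ONSET_OFFSET_MS
    u_search_ms: tuple = umeasure.U_SEARCH_MS
    u_noise_floor_uV: float = umeasure.U_NOISE_FLOOR_UV
    morph_corr_min: float = 0.9
    rr_dev_frac: float = 0.3
    sr_fast_rr_warn_ms: float = 700.0
    max_beats: int | None = None      # cap on qualifying beats (temporal order)
    detector: DetectorParams = field(default_factory=DetectorParams)

    def rr_min_for(self, mode: str) -> float:
        return self.rr_min_sr_ms if mode.upper() == "SR" else self.rr_min_af_ms

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lead_preference"] = list(self.lead_preference)
        d["u_search_ms"] = list(self.u_search_ms)
        return d


@dataclass
class ExtractionResult:
    record_id: str
    mode: str
    peaks: rpeaks.RPeakSeries
    beats: QualifyingBeats
    average: AverageBeat
    measurement: UMeasurement
    params: ExtractParams


def prepare_beats(
    record: ECGRecord, params: ExtractParams | None = None, mode: str | None = None
) -> tuple[ECGRecord, rpeaks.RPeakSeries, QualifyingBeats]:
    """Run detection, ectopic screening, histogram and selection; returns
    the analysed single lead, the flagged peaks and the qualifying beats."""
    p = params or ExtractParams()
    mode = (mode or record.rhythm or "AF").upper()
    lead = select_lead(record, list(p.lead_preference)) if record.n_leads > 1 else record
    peaks = detect_r_peaks(lead, p.detector)
    if len(peaks) == 0:
        raise RuntimeError(f"no R peaks detected in {record.record_id or '<record>'}")
    peaks = flag_ectopics(peaks, lead, rr_dev_frac=p.rr_dev_frac,
                          morph_corr_min=p.morph_corr_min, mode=mode)
    if mode == "SR":
        modal = np.median(peaks.usable_rr_ms()) if len(peaks) > 2 else np.inf
        if modal < p.sr_fast_rr_warn_ms:
            log.warning(
                "fast SR rate (median RR %.0f ms < %.0f ms): the U wave may be "
                "obscured by the following P wave", modal, p.sr_fast_rr_warn_ms,
            )
    hist = compute_rr_histogram(peaks, p.rr_bin_ms)
    beats = select_qualifying_beats(
        peaks, hist, rr_min=p.rr_min_for(mode),
        window_pre_ms=p.window_pre_ms, window_post_ms=p.window_post_ms,
    )
    if p.max_beats is not None and len(beats) > p.max_beats:
        beats.r_indices = beats.r_indices[: p.max_beats]
    return lead, peaks, beats


def extract_u_wave(
    record: ECGRecord, params: ExtractParams | None = None, mode: str | None = None
) -> ExtractionResult:
    """Full extraction on one record; raises with a diagnostic when no beat
    qualifies."""
    p = params or ExtractParams()
    mode = (mode or record.rhythm or "AF").upper()
    lead, peaks, beats = prepare_beats(record, p, mode)
    if len(beats) == 0:
        raise RuntimeError(
            f"zero qualifying beats in {record.record_id or '<record>'}: "
            f"{beats.diagnostics}"
        )
    segments, time_ms = extract_beat_windows(lead, beats)
    avg = compute_average_beat(segments, time_ms, lead.fs, r_indices=beats.r_indices)
    meas = umeasure.measure_u_wave(
        avg, mode=mode,
        qrs_onset_offset_ms=p.qrs_onset_offset_ms,
        p_onset_offset_ms=p.p_onset_offset_ms,
        search_window_ms=tuple(p.u_search_ms),
        noise_floor_uV=p.u_noise_floor_uV,
    )
    return ExtractionResult(record.record_id, mode, peaks, beats, avg, meas, p)
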