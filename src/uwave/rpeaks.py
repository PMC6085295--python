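"""R-wave peak detection and ectopic-beat exclusion.

Detection follows the classic Pan-Tompkins recipe (band-pass, differentiate,
square, moving-window integrate, adaptive threshold) with a final refinement
to the raw-signal maximum within +/-50 ms of the detector fiducial, so that
reported indices sit on the R apex regardless of sampling rate.

Ectopic beats are flagged by QRS morphology correlation against the cohort
median beat template; in sinus rhythm an additional RR-deviation rule
applies (it is meaningless in AF, where RR is irregular by nature).
A flagged beat invalidates both RR intervals touching it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .io_ecg import ECGRecord

log = logging.getLogger(__name__)


@dataclass
class DetectorParams:
    band_low_hz: float = 5.0
    band_high_hz: float = 18.0
    integrate_ms: float = 150.0
    min_rr_ms: float = 250.0      # refractory distance between candidates
    refine_ms: float = 50.0       # half-width of the raw-max refinement window
    threshold_frac: float = 0.15  # of the adaptive envelope level


@dataclass
class RPeakSeries:
    """Detected R peaks for one record.

    ``indices`` are strictly increasing sample indices of R apexes;
    ``ectopic_flags`` marks beats excluded (with their adjacent intervals)
    from all downstream RR statistics.
    """

    indices: np.ndarray
    fs: float
    n_samples: int
    ectopic_flags: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.ectopic_flags is None:
            self.ectopic_flags = np.zeros(len(self.indices), dtype=bool)
        self.ectopic_flags = np.asarray(self.ectopic_flags, dtype=bool)
        if len(self.ectopic_flags) != len(self.indices):
            raise ValueError("ectopic_flags length must match indices")
        if len(self.indices):
            if np.any(np.diff(self.indices) <= 0):
                raise ValueError("R-peak indices must be strictly increasing")
            if self.indices[0] < 0 or self.indices[-1] >= self.n_samples:
                raise ValueError("R-peak index outside record")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def rr_ms(self) -> np.ndarray:
        """All RR intervals in ms; rr_ms[i-1] precedes beat i."""
        return np.diff(self.indices) / self.fs * 1000.0

    @property
    def rr_valid(self) -> np.ndarray:
        """Usable-interval mask: interval (i, i+1) is dropped when either
        endpoint beat is ectopic."""
        e = self.ectopic_flags
        return ~(e[:-1] | e[1:])

    def usable_rr_ms(self) -> np.ndarray:
        return self.rr_ms[self.rr_valid]


def detect_r_peaks(record: ECGRecord, params: DetectorParams | None = None) -> RPeakSeries:
    """Detect R peaks in a single-lead record.

    Returns an empty series (with a logged warning) when no QRS-like
    activity is present, e.g. on a flat signal.
    """
    if record.n_leads != 1:
        raise ValueError("detect_r_peaks expects a single-lead record; use select_lead")
    p = params or DetectorParams()
    x = record.samples[0]
    fs = record.fs
    if np.ptp(x) == 0:
        log.warning("flat signal in %s: no R peaks", record.record_id or "<record>")
        return RPeakSeries(np.empty(0, np.int64), fs, record.n_samples)

    high = min(p.band_high_hz, 0.45 * fs)
    b, a = butter(2, [p.band_low_hz / (fs / 2), high / (fs / 2)], btype="band")
    xf = filtfilt(b, a, x)
    sq = np.gradient(xf) ** 2
    win = max(1, int(round(p.integrate_ms / 1000 * fs)))
    env = np.convolve(sq, np.ones(win) / win, mode="same")

    dist = max(1, int(round(p.min_rr_ms / 1000 * fs)))
    cand, _ = find_peaks(env, distance=dist)
    if len(cand) == 0:
        log.warning("no R peaks detected in %s", record.record_id or "<record>")
        return RPeakSeries(np.empty(0, np.int64), fs, record.n_samples)
    # two-stage adaptive threshold: junk candidates (filter ringing, f-wave)
    # sit orders of magnitude below QRS envelopes, so screen against the
    # tallest candidate first, then re-threshold against the median height
    # of the retained beats (keeps wide, low-slope ectopic complexes)
    heights = env[cand]
    first = heights > p.threshold_frac * heights.max()
    level = np.median(heights[first])
    cand = cand[heights > p.threshold_frac * level]

    # fiducial: squared-slope maximum near the envelope peak, then apex
    # refinement on the raw signal within +/- refine_ms
    half_f = max(1, int(round(0.100 * fs)))
    half_r = max(1, int(round(p.refine_ms / 1000 * fs)))
    idx = []
    for c in cand:
        lo, hi = max(0, c - half_f), min(len(x), c + half_f + 1)
        fid = lo + int(np.argmax(sq[lo:hi]))
        lo, hi = max(0, fid - half_r), min(len(x), fid + half_r + 1)
        idx.append(lo + int(np.argmax(x[lo:hi])))
    idx = np.unique(np.asarray(idx, dtype=np.int64))
    # enforce refractory spacing on refined apexes (keep the taller)
    keep = []
    for i in idx:
        if keep and i - keep[-1] < dist:
            if x[i] > x[keep[-1]]:
                keep[-1] = i
        else:
            keep.append(i)
    return RPeakSeries(np.asarray(keep, dtype=np.int64), fs, record.n_samples)


def _beat_windows(x: np.ndarray, indices: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack beat windows R-half..R+half; beats too close to the edges are
    masked out of template building."""
    ok = (indices - half >= 0) & (indices + half < len(x))
    rows = np.stack([x[i - half : i + half + 1] for i in indices[ok]]) if ok.any() else np.empty((0, 2 * half + 1))
    return rows, ok


def flag_ectopics(
    peaks: RPeakSeries,
    record: ECGRecord,
    rr_dev_frac: float = 0.3,
    morph_corr_min: float = 0.9,
    template_half_ms: float = 60.0,
    mode: str | None = None,
) -> RPeakSeries:
    """Flag ectopic beats; returns a new series with updated flags.

    A beat is ectopic when its QRS window (R +/- ``template_half_ms``)
    correlates with the median beat template below ``morph_corr_min``, or --
    in SR mode only -- when its preceding RR deviates from the local median
    RR by more than ``rr_dev_frac`` (fractional). AF's inherently irregular
    RR series makes the deviation rule meaningless there.
    """
    if len(peaks) < 3:
        log.warning("fewer than 3 peaks: ectopic screening skipped")
        return peaks
    mode = (mode or record.rhythm or "unknown").upper()
    x = record.samples[0]
    half = max(1, int(round(template_half_ms / 1000 * peaks.fs)))
    rows, ok = _beat_windows(x, peaks.indices, half)
    flags = np.zeros(len(peaks), dtype=bool)
    if len(rows) >= 3:
        template = np.median(rows, axis=0)
        t = template - template.mean()
        tn = np.linalg.norm(t)
        corrs = np.full(len(peaks), 1.0)
        j = 0
        for i in range(len(peaks)):
            if not ok[i]:
                continue
            w = rows[j] - rows[j].mean()
            j += 1
            wn = np.linalg.norm(w)
            corrs[i] = (w @ t) / (wn * tn) if wn > 0 and tn > 0 else np.nan
        flags |= ~(corrs >= morph_corr_min) & ok  # NaN corr counts as ectopic

    if mode == "SR":
        rr = peaks.rr_ms
        med = np.median(rr)
        for i in range(1, len(peaks)):
            local = rr[max(0, i - 6) : i + 5]
            m = np.median(local) if len(local) else med
            if abs(rr[i - 1] - m) > rr_dev_frac * m:
                flags[i] = True

    n = int(flags.sum())
    if n:
        log.info("flagged %d ectopic beat(s)", n)
    return replace(peaks, ectopic_flags=flags)


def write_annotations(peaks: RPeakSeries, path) -> None:
    """Export peaks for external review as a text annotation table
    (sample index, symbol N/V, one row per beat)."""
    from pathlib import Path

    lines = ["sample\tsymbol"]
    for i, e in zip(peaks.indices, peaks.ectopic_flags):
        lines.append(f"{int(i)}\t{'V' if e else 'N'}")
    Path(path).write_text("\n".join(lines) + "\n")
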