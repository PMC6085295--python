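"""Qualifying-beat selection from the preceding-RR histogram.

The average beat is built only from beats whose preceding RR interval falls
in the modal 100 ms histogram bin (RR_mode +/- 50 ms) and whose following RR
exceeds RR_min, so the next QRS cannot contaminate the averaged U wave.
Bin edges are anchored at integer multiples of the bin width from 0 and
bins are half-open [left, right); ties in the mode go to the shorter-RR bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_ecg import ECGRecord
from .rpeaks import RPeakSeries

log = logging.getLogger(__name__)

RR_BIN_MS = 100.0
RR_MIN_AF_MS = 650.0
RR_MIN_SR_MS = 800.0
WINDOW_PRE_MS = 250.0
WINDOW_POST_MS = 650.0


class EmptyHistogramError(ValueError):
    """No usable RR intervals to bin."""


@dataclass
class RRHistogram:
    """Histogram of usable preceding-RR intervals.

    ``bin_edges`` has one more element than ``counts``; bin j spans
    [bin_edges[j], bin_edges[j+1]).  ``mode_bin`` indexes the fullest bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mode_bin: int
    rr_bin: float

    @property
    def mode_interval(self) -> tuple[float, float]:
        return float(self.bin_edges[self.mode_bin]), float(self.bin_edges[self.mode_bin + 1])

    @property
    def rr_mode_center(self) -> float:
        lo, hi = self.mode_interval
        return 0.5 * (lo + hi)


@dataclass
class QualifyingBeats:
    """Beats admitted to the average, in temporal order, plus the criteria
    actually applied and per-criterion failure counts for diagnostics."""

    r_indices: np.ndarray
    fs: float
    window_pre_ms: float
    window_post_ms: float
    criteria: dict
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r_indices = np.asarray(self.r_indices, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.r_indices)

    @property
    def pre_samples(self) -> int:
        return int(round(self.window_pre_ms / 1000 * self.fs))

    @property
    def post_samples(self) -> int:
        return int(round(self.window_post_ms / 1000 * self.fs))


def compute_rr_histogram(peaks: RPeakSeries, rr_bin: float = RR_BIN_MS) -> RRHistogram:
    """Bin the usable preceding-RR intervals into half-open ``rr_bin``-wide
    bins anchored at 0 and locate the modal bin."""
    rr = peaks.usable_rr_ms()
    if len(rr) == 0:
        raise EmptyHistogramError("no usable RR intervals (too few peaks or all ectopic-adjacent)")
    lo = int(np.floor(rr.min() / rr_bin))
    hi = int(np.floor(rr.max() / rr_bin)) + 1
    edges = np.arange(lo, hi + 1) * rr_bin
    which = np.floor(rr / rr_bin).astype(int) - lo
    counts = np.bincount(which, minlength=hi - lo)
    mode_bin = int(np.argmax(counts))  # argmax takes the first -> shorter RR on ties
    return RRHistogram(edges, counts, mode_bin, float(rr_bin))


def select_qualifying_beats(
    peaks: RPeakSeries,
    hist: RRHistogram,
    rr_min: float = RR_MIN_AF_MS,
    window_pre_ms: float = WINDOW_PRE_MS,
    window_post_ms: float = WINDOW_POST_MS,
) -> QualifyingBeats:
    """Select beats for averaging.

    Beat i qualifies when all of:

    * its preceding RR lies in the modal bin [RR_mode - rr_bin/2,
      RR_mode + rr_bin/2)  (half-open),
    * its following RR is strictly greater than ``rr_min``,
    * neither it nor either neighbour is ectopic (a removed interval can
      serve as neither preceding nor following RR),
    * the beat window R - window_pre .. R + window_post lies inside the
      record.

    When nothing qualifies an empty result is returned whose diagnostics
    report how many beats failed each criterion.
    """
    if rr_min <= 0:
        raise ValueError("rr_min must be positive")
    lo, hi = hist.mode_interval
    rr = peaks.rr_ms
    ect = peaks.ectopic_flags
    pre = int(round(window_pre_ms / 1000 * peaks.fs))
    post = int(round(window_post_ms / 1000 * peaks.fs))
    fails = {"preceding_rr": 0, "following_rr": 0, "ectopic_adjacent": 0, "window": 0, "no_rr_pair": 0}
    chosen = []
    for i in range(len(peaks)):
        if i == 0 or i == len(peaks) - 1:
            fails["no_rr_pair"] += 1
            continue
        ok = True
        if ect[i] or ect[i - 1] or ect[i + 1]:
            fails["ectopic_adjacent"] += 1
            ok = False
        if not (lo <= rr[i - 1] < hi):
            fails["preceding_rr"] += 1
            ok = False
        if not (rr[i] > rr_min):
            fails["following_rr"] += 1
            ok = False
        r = peaks.indices[i]
        if r - pre < 0 or r + post >= peaks.n_samples:
            fails["window"] += 1
            ok = False
        if ok:
            chosen.append(peaks.indices[i])
    if not chosen:
        log.warning("zero qualifying beats; failure counts: %s", fails)
    return QualifyingBeats(
        r_indices=np.asarray(chosen, dtype=np.int64),
        fs=peaks.fs,
        window_pre_ms=window_pre_ms,
        window_post_ms=window_post_ms,
        criteria={
            "rr_mode_center": hist.rr_mode_center,
            "rr_bin": hist.rr_bin,
            "rr_min": float(rr_min),
        },
        diagnostics={"n_failed": fails, "n_beats_total": len(peaks)},
    )


def extract_beat_windows(record: ECGRecord, beats: QualifyingBeats) -> tuple[np.ndarray, np.ndarray]:
    """Stack R-aligned beat windows.

    Returns ``(segments, time_ms)`` where ``segments`` has shape
    (n_beats, n_window_samples) and ``time_ms`` is the shared R-relative
    time axis; sample ``beats.pre_samples`` is the R apex.
    """
    if len(beats) == 0:
        raise ValueError("no qualifying beats to extract")
    x = record.samples[0]
    pre, post = beats.pre_samples, beats.post_samples
    rows = []
    for r in beats.r_indices:
        if r - pre < 0 or r + post >= len(x):
            log.warning("window for beat at sample %d exceeds record; dropped", r)
            continue
        rows.append(x[r - pre : r + post + 1])
    segments = np.stack(rows)
    time_ms = (np.arange(-pre, post + 1)) / record.fs * 1000.0
    return segments, time_ms
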