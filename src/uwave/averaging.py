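"""Beat averaging -- the noise-reduction core.

The average beat is the per-sample arithmetic mean of the R-aligned
qualifying-beat windows. Components uncorrelated with the ventricular cycle
(the atrial fibrillatory wave, EMG, powerline residue) shrink roughly as
1/sqrt(N) while the beat-locked waves, including the low-amplitude U wave,
are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AverageBeat:
    """Mean beat on an R-relative time axis (ms), amplitudes in uV."""

    time_ms: np.ndarray
    amplitude_uV: np.ndarray
    fs: float
    n_beats_used: int
    contributing_r_indices: np.ndarray = field(default=None)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.amplitude_uV = np.asarray(self.amplitude_uV, dtype=float)
        if self.time_ms.shape != self.amplitude_uV.shape:
            raise ValueError("time axis and amplitude must have equal length")
        if self.n_beats_used < 1:
            raise ValueError("an average beat needs at least one contributing beat")
        if self.contributing_r_indices is None:
            self.contributing_r_indices = np.empty(0, dtype=np.int64)

    @property
    def r_sample(self) -> int:
        """Index of the R apex (time 0) on the window axis."""
        return int(np.argmin(np.abs(self.time_ms)))

    def sample_at(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.time_ms - t_ms)))


def compute_average_beat(
    segments: np.ndarray,
    time_ms: np.ndarray,
    fs: float,
    r_indices: np.ndarray | None = None,
    robust: bool = False,
) -> AverageBeat:
    """Average aligned beat segments.

    Parameters
    ----------
    segments : ndarray, shape (n_beats, n_samples)
        R-aligned beat windows in uV; all rows must have equal length.
    time_ms : ndarray
        Shared R-relative time axis.
    robust : bool
        Use the per-sample median instead of the mean. Off by default; the
        canonical algorithm is the plain mean.
    """
    segments = np.asarray(segments, dtype=float)
    if segments.ndim != 2 or segments.shape[0] < 1:
        raise ValueError("segments must be a non-empty 2-D array of aligned beats")
    if segments.shape[1] != len(time_ms):
        raise ValueError(
            f"segment length {segments.shape[1]} does not match time axis {len(time_ms)}"
        )
    avg = np.median(segments, axis=0) if robust else segments.mean(axis=0)
    return AverageBeat(
        time_ms=np.asarray(time_ms, dtype=float),
        amplitude_uV=avg,
        fs=fs,
        n_beats_used=segments.shape[0],
        contributing_r_indices=(
            np.asarray(r_indices, dtype=np.int64) if r_indices is not None else None
        ),
        provenance={"robust": robust},
    )


def highpass_baseline(segments: np.ndarray, fs: float, cutoff_hz: float = 0.5) -> np.ndarray:
    """Optional zero-phase high-pass for baseline wander, applied per
    segment before averaging. Not part of the default pipeline."""
    from scipy.signal import butter, filtfilt

    b, a = butter(2, cutoff_hz / (fs / 2), btype="high")
    return filtfilt(b, a, segments, axis=-1)


def export_average_csv(avg: AverageBeat, path) -> None:
    import pandas as pd

    pd.DataFrame({"time_ms": avg.time_ms, "amplitude_uV": avg.amplitude_uV}).to_csv(
        path, index=False, float_format="%.6f"
    )
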