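"""U-wave measurement on an average beat.

Baseline is the mean of a 10-sample window in the electrically quiescent
period ending at the estimated QRS onset (AF) or P-wave onset (SR). The U
apex is the extremum of the baseline-subtracted amplitude inside a search
window after the T wave; the reported amplitude is signed baseline-to-peak,
negative for an inverted U wave.

The presence call is an automatic surrogate for visual assessment: the apex
must exceed a noise floor and be a genuine interior local extremum, not a
window-edge sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .averaging import AverageBeat
from .io_ecg import ConfigurationError

log = logging.getLogger(__name__)

BASELINE_N_SAMPLES = 10
QRS_ONSET_OFFSET_MS = 60.0   # AF mode: QRS onset estimated at R - 60 ms
P_ONSET_OFFSET_MS = 220.0    # SR mode: P onset estimated at R - 220 ms
# Upper bound keeps clear of the earliest admissible following QRS: with
# RR_min = 650 ms the next R may sit at 651 ms and its Q onset near 595 ms,
# so searching past ~590 ms picks up next-QRS contamination in the average.
U_SEARCH_MS = (450.0, 590.0)
U_NOISE_FLOOR_UV = 10.0


@dataclass
class UMeasurement:
    """Baseline level, U apex location and signed baseline-to-peak amplitude."""

    baseline_uV: float
    u_peak_time_ms: float
    u_amp_uV: float
    u_present: bool
    search_window_ms: tuple[float, float]
    mode: str = "AF"
    params: dict | None = None

    def to_dict(self) -> dict:
        return {
            "baseline_uV": self.baseline_uV,
            "u_peak_time_ms": self.u_peak_time_ms,
            "u_amp_uV": self.u_amp_uV,
            "u_present": bool(self.u_present),
            "search_window_ms": list(self.search_window_ms),
            "mode": self.mode,
            "params": self.params or {},
            "u_present_rule": "automatic surrogate (noise floor + interior extremum), not a visual call",
        }


def estimate_baseline(
    avg: AverageBeat,
    mode: str = "AF",
    qrs_onset_offset_ms: float = QRS_ONSET_OFFSET_MS,
    p_onset_offset_ms: float = P_ONSET_OFFSET_MS,
    n_samples: int = BASELINE_N_SAMPLES,
    flatness_warn_factor: float = 3.0,
) -> float:
    """Mean of ``n_samples`` consecutive samples ending at the estimated
    onset (QRS onset in AF mode, P onset in SR mode).

    The window duration therefore scales with the sampling rate (10 samples
    is 78 ms at 128 Hz, 20 ms at 500 Hz). A flatness check warns when the
    window looks electrically active.
    """
    offset = qrs_onset_offset_ms if mode.upper() == "AF" else p_onset_offset_ms
    onset = avg.r_sample - int(round(offset / 1000 * avg.fs))
    start = onset - n_samples
    if start < 0 or onset > len(avg.amplitude_uV):
        need = (n_samples / avg.fs * 1000) + offset
        raise ConfigurationError(
            f"baseline window [{start}, {onset}) outside the average beat; "
            f"window_pre_ms must be at least {need:.0f} ms"
        )
    w = avg.amplitude_uV[start:onset]
    pre_r = avg.amplitude_uV[: max(avg.r_sample - int(round(offset / 1000 * avg.fs)), 1)]
    if pre_r.size > n_samples and np.std(w) > flatness_warn_factor * max(np.std(pre_r), 1e-12):
        log.warning(
            "baseline window looks electrically active (sigma %.1f uV); "
            "check the onset offset", np.std(w),
        )
    return float(np.mean(w))


def _point_apex(t, amp, sel, baseline):
    """Raw extremum of |amplitude - baseline| inside the window."""
    dev = amp[sel] - baseline
    k = int(np.argmax(np.abs(dev)))
    apex = sel[k]
    u_amp = float(dev[k])
    interior = 0 < k < len(sel) - 1
    is_extremum = False
    if 0 < apex < len(t) - 1:
        d = amp - baseline
        if u_amp >= 0:
            is_extremum = d[apex] >= d[apex - 1] and d[apex] >= d[apex + 1]
        else:
            is_extremum = d[apex] <= d[apex - 1] and d[apex] <= d[apex + 1]
    return float(t[apex]), u_amp, interior and is_extremum


def _fit_apex(t, amp, sel, baseline):
    """Gaussian-bump fit over the search window.

    The model ``b + c (t - t0) + A * exp(-(t - tau)^2 / (2 w^2))`` absorbs
    the local offset and slope (T-wave tail, slow residual) into the linear
    part and reads the apex value off the fitted curve, which averages
    residual noise over the whole window instead of a single sample.
    Returns None when the fit does not converge or the apex pins to a
    window edge; the caller then falls back to the raw extremum.
    """
    from scipy.optimize import curve_fit

    tw, yw = t[sel], amp[sel]
    dev = yw - baseline
    k0 = int(np.argmax(np.abs(dev)))
    a0 = float(dev[k0])
    if a0 == 0:
        return None
    t0 = float(tw.mean())
    span = tw[-1] - tw[0]

    def model(x, b, c, a, tau, w):
        return b + c * (x - t0) + a * np.exp(-0.5 * ((x - tau) / w) ** 2)

    try:
        popt, _ = curve_fit(
            model, tw, yw,
            p0=[baseline, 0.0, a0, float(tw[k0]), 40.0],
            bounds=([-np.inf, -np.inf, -np.inf, tw[0], 15.0],
                    [np.inf, np.inf, np.inf, tw[-1], 1.5 * span]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return None
    b, c, a, tau, w = popt
    margin = (tw[1] - tw[0]) / 2
    if not (tw[0] + margin < tau < tw[-1] - margin):
        return None  # apex pinned to the window edge: not a genuine bump
    u_amp = float(b + c * (tau - t0) + a - baseline)
    return float(tau), u_amp, True


def measure_u_amplitude(
    avg: AverageBeat,
    baseline: float,
    search_window_ms: tuple[float, float] = U_SEARCH_MS,
    noise_floor_uV: float = U_NOISE_FLOOR_UV,
    mode: str = "AF",
    apex_method: str = "fit",
) -> UMeasurement:
    """Locate the U apex and measure its baseline-to-peak amplitude.

    ``apex_method="fit"`` (default) fits a local Gaussian bump and reports
    its apex; ``"point"`` takes the raw sample of maximum
    |amplitude - baseline|. The fit falls back to the point reading when it
    cannot converge (e.g. a flat beat). The upper search bound is clipped
    to the end of the beat window; a lower bound beyond the window is an
    error.
    """
    t = avg.time_ms
    lo, hi = float(search_window_ms[0]), float(search_window_ms[1])
    if lo >= t[-1]:
        raise ConfigurationError(
            f"U search window starts at {lo} ms but the beat window ends at {t[-1]:.0f} ms"
        )
    hi_eff = min(hi, float(t[-1]))
    sel = np.flatnonzero((t >= lo) & (t <= hi_eff))
    method_used = "point"
    fit = _fit_apex(t, avg.amplitude_uV, sel, baseline) if apex_method == "fit" else None
    if fit is not None:
        u_time, u_amp, genuine = fit
        method_used = "fit"
    else:
        u_time, u_amp, genuine = _point_apex(t, avg.amplitude_uV, sel, baseline)
    present = bool(abs(u_amp) > noise_floor_uV and genuine)
    return UMeasurement(
        baseline_uV=float(baseline),
        u_peak_time_ms=u_time,
        u_amp_uV=u_amp,
        u_present=present,
        search_window_ms=(lo, hi_eff),
        mode=mode,
        params={"noise_floor_uV": noise_floor_uV, "apex_method": method_used},
    )


def measure_u_wave(
    avg: AverageBeat,
    mode: str = "AF",
    qrs_onset_offset_ms: float = QRS_ONSET_OFFSET_MS,
    p_onset_offset_ms: float = P_ONSET_OFFSET_MS,
    search_window_ms: tuple[float, float] = U_SEARCH_MS,
    noise_floor_uV: float = U_NOISE_FLOOR_UV,
    apex_method: str = "fit",
) -> UMeasurement:
    """Convenience: baseline estimation followed by amplitude measurement."""
    baseline = estimate_baseline(
        avg, mode=mode,
        qrs_onset_offset_ms=qrs_onset_offset_ms,
        p_onset_offset_ms=p_onset_offset_ms,
    )
    return measure_u_amplitude(
        avg, baseline,
        search_window_ms=search_window_ms,
        noise_floor_uV=noise_floor_uV,
        mode=mode,
        apex_method=apex_method,
    )
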