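"""Synthetic AF and SR ECG generator with ground truth.

Beats are sums of Gaussian kernels (Q, R, S, T, plus U and, in sinus
rhythm, P), placed at beat times drawn from a truncated-lognormal RR model
(AF) or a near-constant RR model (SR). AF records carry a continuous
fibrillatory wave: a sinusoid whose instantaneous frequency performs an
Ornstein-Uhlenbeck walk so its phase never locks to the beat times. White
(EMG-like) and powerline noise are added on top. Every record comes with
exact ground truth: R-apex samples, ectopic flags and the planted U
amplitude -- which is what makes each pipeline stage testable without
clinical recordings.

All simulation is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_ecg import ECGRecord


class SynthValidationError(ValueError):
    """The requested configuration cannot produce a physiologic record."""


# (center_ms relative to R, sigma_ms, amplitude_uV)
DEFAULT_QRST = (
    (-35.0, 7.0, -100.0),   # Q
    (0.0, 12.0, 1000.0),    # R
    (35.0, 10.0, -180.0),   # S
    (300.0, 55.0, 300.0),   # T
)


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the package's standard study
    conditions (500 Hz lead-V4-like morphology, AF RR mean 780 ms with the
    modal 100 ms bin passing roughly a quarter of the beats, 80 uV f-wave,
    20 uV white noise, 5 uV powerline)."""

    fs: float = 500.0
    duration_s: float = 240.0
    rhythm: str = "AF"
    # RR model: truncated lognormal for AF, near-constant normal for SR
    rr_mean_ms: float = 780.0
    rr_sd_ms: float = 150.0
    rr_floor_ms: float = 400.0
    # beat morphology
    qrst: tuple = DEFAULT_QRST
    u_delay_ms: float = 520.0
    u_width_ms: float = 40.0
    u_amp_uV: float = 40.0
    # SR only: P apex precedes R by 140 ms (P onset ~ -215 ms, PR ~ 160 ms),
    # so the default pre-P baseline window stays clear of the P foot
    p_lead_ms: float = 140.0
    p_width_ms: float = 25.0
    p_amp_uV: float = 100.0
    # fibrillatory wave (AF only); amplitude is peak-to-peak, so the default
    # oscillates +/-40 uV around baseline -- comparable to the U wave itself,
    # which is what makes the U wave indiscernible on the raw trace
    f_freq_hz: float = 6.0
    f_amp_uV: float = 80.0
    f_freq_jitter: float = 0.5   # OU diffusion, Hz per sqrt(s)
    # noise
    white_sd_uV: float = 20.0
    powerline_hz: float = 50.0
    powerline_amp_uV: float = 5.0
    # ectopic beats
    n_ectopics: int = 0
    ectopic_width_scale: float = 2.5
    ectopic_amp_scale: float = 0.8
    seed: int | None = None

    def sr_defaults(self) -> "SynthConfig":
        """AF defaults re-tuned for sinus rhythm (regular, slightly slower
        RR so the following P wave stays clear of the U search window)."""
        return replace(self, rhythm="SR", rr_mean_ms=950.0, rr_sd_ms=25.0,
                       f_amp_uV=0.0)


@dataclass
class GroundTruth:
    """Exact simulation annotations for validating the pipeline."""

    r_samples: np.ndarray        # every beat's R apex sample, ectopics included
    ectopic: np.ndarray          # per-beat flag
    u_amp_uV: float              # planted U amplitude
    u_delay_ms: float
    fs: float
    rhythm: str

    def to_dict(self) -> dict:
        return {
            "r_samples": [int(i) for i in self.r_samples],
            "ectopic": [bool(b) for b in self.ectopic],
            "u_amp_uV": self.u_amp_uV,
            "u_delay_ms": self.u_delay_ms,
            "fs": self.fs,
            "rhythm": self.rhythm,
        }


def _beat_kernels(config: SynthConfig, ectopic: bool = False) -> list[tuple[float, float, float]]:
    ks = list(config.qrst)
    if ectopic:
        ks = [(c, w * config.ectopic_width_scale, a * config.ectopic_amp_scale)
              for c, w, a in ks[:3]]  # wide QRS, discordant (no T)
        ks.append((250.0, 80.0, -0.4 * config.qrst[3][2]))
        return ks
    ks.append((config.u_delay_ms, config.u_width_ms, config.u_amp_uV))
    if config.rhythm.upper() == "SR":
        ks.append((-config.p_lead_ms, config.p_width_ms, config.p_amp_uV))
    return ks


def beat_template(config: SynthConfig, time_ms: np.ndarray) -> np.ndarray:
    """Noiseless single-beat waveform (no neighbours) on an R-relative axis."""
    t = np.asarray(time_ms, dtype=float)
    out = np.zeros_like(t)
    for c, w, a in _beat_kernels(config):
        out += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


def _draw_rr_ms(config: SynthConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if config.rr_sd_ms == 0:
        return np.full(n, config.rr_mean_ms)
    if config.rhythm.upper() == "AF":
        s2 = np.log1p((config.rr_sd_ms / config.rr_mean_ms) ** 2)
        mu = np.log(config.rr_mean_ms) - s2 / 2
        rr = rng.lognormal(mu, np.sqrt(s2), size=n)
        for _ in range(100):
            low = rr < config.rr_floor_ms
            if not low.any():
                break
            rr[low] = rng.lognormal(mu, np.sqrt(s2), size=int(low.sum()))
        return rr
    rr = rng.normal(config.rr_mean_ms, config.rr_sd_ms, size=n)
    return np.maximum(rr, config.rr_floor_ms)


def _f_wave(config: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-sinusoid with OU frequency jitter; phase continuous, never
    locked to beat times."""
    dt = 1.0 / config.fs
    theta = 0.3
    xi = rng.standard_normal(n)
    f = np.empty(n)
    f[0] = config.f_freq_hz
    drift = config.f_freq_jitter * np.sqrt(dt)
    for k in range(1, n):
        f[k] = f[k - 1] + theta * (config.f_freq_hz - f[k - 1]) * dt + drift * xi[k]
    np.clip(f, 3.0, 12.0, out=f)
    phase = 2 * np.pi * np.cumsum(f) * dt + rng.uniform(0, 2 * np.pi)
    return 0.5 * config.f_amp_uV * np.sin(phase)  # f_amp_uV is peak-to-peak


def simulate_record(config: SynthConfig, seed: int | None = None) -> tuple[ECGRecord, GroundTruth]:
    """Simulate a single-lead record plus ground-truth annotations.

    ``seed`` overrides ``config.seed``; identical (config, seed) pairs give
    bit-identical output.
    """
    rhythm = config.rhythm.upper()
    if rhythm not in ("AF", "SR"):
        raise SynthValidationError(f"rhythm must be AF or SR, got {config.rhythm!r}")
    # beats with short RR simply have the next QRS overrunning the U wave
    # (the RR_min selection rule exists for exactly that); infeasible is a
    # U apex beyond the *typical* cycle length
    typ_rr = config.rr_mean_ms if rhythm == "AF" else config.rr_mean_ms - 4 * config.rr_sd_ms
    if config.u_delay_ms + config.u_width_ms >= typ_rr:
        raise SynthValidationError(
            f"U delay {config.u_delay_ms} ms reaches beyond the typical RR ({typ_rr:.0f} ms)"
        )
    if config.duration_s * 1000 < 3 * config.rr_mean_ms:
        raise SynthValidationError("duration too short for three beats")
    rng = np.random.default_rng(seed if seed is not None else config.seed)

    n = int(round(config.duration_s * config.fs))
    n_beats_max = int(config.duration_s * 1000 / config.rr_floor_ms) + 2
    rr = _draw_rr_ms(config, rng, n_beats_max)
    t_beats = 600.0 + np.concatenate(([0.0], np.cumsum(rr)))
    t_beats = t_beats[t_beats < config.duration_s * 1000 - 800.0]
    r_samples = np.round(t_beats / 1000 * config.fs).astype(np.int64)
    ect = np.zeros(len(r_samples), dtype=bool)

    # insert premature wide beats between evenly spaced host beats
    if config.n_ectopics > 0:
        if len(r_samples) < config.n_ectopics + 4:
            raise SynthValidationError("too few beats to host the requested ectopics")
        hosts = np.linspace(2, len(r_samples) - 3, config.n_ectopics).astype(int)
        extra = []
        for h in hosts:
            gap = r_samples[h + 1] - r_samples[h]
            extra.append(r_samples[h] + int(round(0.55 * gap)))
        r_samples = np.concatenate([r_samples, extra])
        ect = np.concatenate([ect, np.ones(len(extra), dtype=bool)])
        order = np.argsort(r_samples)
        r_samples, ect = r_samples[order], ect[order]

    x = np.zeros(n)
    dt_ms = 1000.0 / config.fs
    for s, is_ect in zip(r_samples, ect):
        for c, w, a in _beat_kernels(config, ectopic=bool(is_ect)):
            half = int(np.ceil(4 * w / dt_ms))
            c_idx = s + int(round(c / dt_ms))
            lo, hi = max(0, c_idx - half), min(n, c_idx + half + 1)
            if lo >= hi:
                continue
            t_rel = (np.arange(lo, hi) - s) * dt_ms
            x[lo:hi] += a * np.exp(-0.5 * ((t_rel - c) / w) ** 2)

    if rhythm == "AF" and config.f_amp_uV != 0:
        x += _f_wave(config, n, rng)
    if config.powerline_amp_uV != 0:
        t = np.arange(n) / config.fs
        x += config.powerline_amp_uV * np.sin(
            2 * np.pi * config.powerline_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if config.white_sd_uV != 0:
        x += rng.normal(0, config.white_sd_uV, size=n)

    rec = ECGRecord(
        samples=x[np.newaxis, :],
        fs=config.fs,
        lead_names=["V4"],
        rhythm=rhythm,
        record_id=f"synth-{rhythm.lower()}-{seed if seed is not None else config.seed}",
    )
    truth = GroundTruth(r_samples, ect, config.u_amp_uV, config.u_delay_ms,
                        config.fs, rhythm)
    return rec, truth


@dataclass
class CohortPatient:
    patient_id: str
    af_record: ECGRecord
    af_truth: GroundTruth
    sr_record: ECGRecord
    sr_truth: GroundTruth


def simulate_cohort(
    n_patients: int,
    af_minus_sr_uamp_uV: float = 18.0,
    seed: int | None = None,
    base_config: SynthConfig | None = None,
    sr_amp_mean_uV: float = 37.0,
    sr_amp_sd_uV: float = 10.0,
) -> list[CohortPatient]:
    """Paired AF/SR records per synthetic patient.

    Each patient's SR U amplitude is drawn around ``sr_amp_mean_uV``
    (floored at 15 uV) and the AF record plants exactly that amplitude plus
    the requested paired offset; rhythm features (irregular RR, f-wave vs
    P waves) differ as in real paroxysmal-AF pairs.
    """
    if n_patients < 2:
        raise SynthValidationError("a cohort needs at least 2 patients")
    base = base_config or SynthConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients)
    out = []
    for p, child in enumerate(children):
        s_amp, s_af, s_sr = child.generate_state(3) % (2**31)
        amp_rng = np.random.default_rng(int(s_amp))
        sr_amp = max(15.0, amp_rng.normal(sr_amp_mean_uV, sr_amp_sd_uV))
        af_cfg = replace(base, rhythm="AF", u_amp_uV=sr_amp + af_minus_sr_uamp_uV)
        sr_cfg = replace(base, u_amp_uV=sr_amp).sr_defaults()
        af_rec, af_tr = simulate_record(af_cfg, seed=int(s_af))
        sr_rec, sr_tr = simulate_record(sr_cfg, seed=int(s_sr))
        pid = f"patient-{p:02d}"
        af_rec.record_id, sr_rec.record_id = f"{pid}-af", f"{pid}-sr"
        out.append(CohortPatient(pid, af_rec, af_tr, sr_rec, sr_tr))
    return out


def simulate_amplitude_pairs(
    n_pairs: int,
    delta_uV: float = 18.0,
    diff_sd_uV: float = 25.0,
    base_mean_uV: float = 37.0,
    base_sd_uV: float = 28.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (AF, SR) U-amplitude draws from the cohort amplitude model,
    without waveform synthesis -- the fast path for calibrating the paired
    statistics (the per-pair difference is N(delta, diff_sd))."""
    rng = np.random.default_rng(seed)
    base = rng.normal(base_mean_uV, base_sd_uV, size=n_pairs)
    diff = rng.normal(delta_uV, diff_sd_uV, size=n_pairs)
    return base + diff, base
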