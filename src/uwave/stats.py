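"""Validation-study statistics.

Paired AF/SR comparisons per patient: McNemar's test on the U-wave
presence contingency table (exact binomial on the discordant pairs by
default) and a two-sided paired t-test on the amplitudes. All tests are
two-sided with alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar


@dataclass
class PresencePair:
    """One patient's U-wave presence calls in AF and SR, made with
    identical measurement parameters apart from the rhythm mode."""

    record_id: str
    u_present_af: bool
    u_present_sr: bool


@dataclass
class McNemarResult:
    table: np.ndarray          # rows AF yes/no, cols SR yes/no
    b: int                     # AF yes / SR no
    c: int                     # AF no / SR yes
    statistic: float
    p_value: float
    degenerate: bool           # no discordant pairs; p = 1 by convention
    method: str

    def to_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "discordant_b": self.b,
            "discordant_c": self.c,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
            "method": self.method,
        }


def mcnemar_presence(pairs: list[PresencePair], exact: bool = True) -> McNemarResult:
    """McNemar's test of paired U-wave presence in AF vs SR.

    ``exact=True`` (default) uses the exact binomial test on the discordant
    counts; ``exact=False`` uses the chi-square variant with continuity
    correction. With zero discordant pairs the test carries no information
    and p = 1 is returned with the degenerate flag set.
    """
    if not pairs:
        raise ValueError("at least one presence pair required")
    af = np.array([p.u_present_af for p in pairs], dtype=bool)
    sr = np.array([p.u_present_sr for p in pairs], dtype=bool)
    table = np.array([
        [int(np.sum(af & sr)), int(np.sum(af & ~sr))],
        [int(np.sum(~af & sr)), int(np.sum(~af & ~sr))],
    ])
    b, c = int(table[0, 1]), int(table[1, 0])
    method = "exact-binomial" if exact else "chi2-corrected"
    if b + c == 0:
        return McNemarResult(table, b, c, 0.0, 1.0, True, method)
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return McNemarResult(table, b, c, float(res.statistic), float(res.pvalue),
                         False, method)


@dataclass
class PairedAmplitudeResult:
    n: int
    mean_af_uV: float
    sd_af_uV: float
    mean_sr_uV: float
    sd_sr_uV: float
    mean_diff_uV: float
    sd_diff_uV: float
    t_statistic: float
    p_value: float
    degenerate: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def paired_amplitude_test(af_amps, sr_amps) -> PairedAmplitudeResult:
    """Descriptives and a two-sided paired t-test of AF vs SR U amplitudes
    (uV per patient, paired by patient). Identical vectors (zero-variance
    differences) return p = 1 with the degenerate flag."""
    af = np.asarray(af_amps, dtype=float)
    sr = np.asarray(sr_amps, dtype=float)
    if af.shape != sr.shape or af.ndim != 1:
        raise ValueError(f"paired vectors must be 1-D and equal length, got {af.shape} vs {sr.shape}")
    if len(af) < 2:
        raise ValueError("paired t-test needs n >= 2")
    diff = af - sr
    if np.allclose(diff.std(), 0):
        degenerate = True
        if np.allclose(diff, diff[0]) and not np.allclose(diff[0], 0):
            t, p = np.inf, 0.0   # exact constant shift
        else:
            t, p = 0.0, 1.0
    else:
        degenerate = False
        t, p = sps.ttest_rel(af, sr)
    return PairedAmplitudeResult(
        n=len(af),
        mean_af_uV=float(af.mean()), sd_af_uV=float(af.std(ddof=1)),
        mean_sr_uV=float(sr.mean()), sd_sr_uV=float(sr.std(ddof=1)),
        mean_diff_uV=float(diff.mean()), sd_diff_uV=float(diff.std(ddof=1)),
        t_statistic=float(t), p_value=float(p), degenerate=degenerate,
    )
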