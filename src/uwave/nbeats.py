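"""Number-of-beats study protocol.

The first 100 qualifying beats are split into 10 contiguous groups of 10.
For each averaging size N = 10k on the grid {100, 90, ..., 10}, 10
sub-trials average k circularly-contiguous groups (g_s .. g_{s+k-1}, wrap
modulo 10), so that across the sub-trials every beat is used and each group
is used exactly k times. The U amplitude of each sub-trial's average beat
is measured with identical parameters and compared to the single 100-beat
reference: delta_u_amp = u_amp(N) - u_amp(100). Residual noise inflates the
measured amplitude, so delta_u_amp quantifies extraction quality as N falls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import umeasure
from .averaging import compute_average_beat
from .beat_select import QualifyingBeats, extract_beat_windows
from .io_ecg import ECGRecord
from .pipeline import ExtractParams

log = logging.getLogger(__name__)

NBEATS_GRID = (100, 90, 80, 70, 60, 50, 40, 30, 20, 10)
N_GROUPS = 10
GROUP_SIZE = 10


class InsufficientBeatsError(ValueError):
    pass


def partition_groups(beats: QualifyingBeats) -> list[np.ndarray]:
    """Split the first 100 qualifying beats (temporal order) into 10
    contiguous groups of 10; later beats are unused."""
    need = N_GROUPS * GROUP_SIZE
    if len(beats) < need:
        raise InsufficientBeatsError(
            f"need {need} qualifying beats, found {len(beats)} "
            f"(short by {need - len(beats)})"
        )
    first = beats.r_indices[:need]
    return [first[g * GROUP_SIZE : (g + 1) * GROUP_SIZE] for g in range(N_GROUPS)]


def subtrial_groups(n_beats: int, subtrial: int) -> tuple[int, ...]:
    """0-based group indices used by a sub-trial (1-based) at a given N;
    circular-contiguous: sub-trial s takes groups s-1 .. s-1+k-1 mod 10."""
    if n_beats % GROUP_SIZE or not GROUP_SIZE <= n_beats <= N_GROUPS * GROUP_SIZE:
        raise ValueError(f"n_beats must be one of {NBEATS_GRID}, got {n_beats}")
    k = n_beats // GROUP_SIZE
    return tuple((subtrial - 1 + j) % N_GROUPS for j in range(k))


def run_subtrials(
    record: ECGRecord,
    beats: QualifyingBeats,
    params: ExtractParams | None = None,
    n_beats_grid: tuple[int, ...] = NBEATS_GRID,
    mode: str = "AF",
) -> pd.DataFrame:
    """All sub-trials for one record, as a long DataFrame.

    Columns: record_id, n_beats, subtrial, groups_used, n_segments,
    u_amp_uV, delta_u_amp_uV, baseline_uV, u_peak_time_ms. At N = 100 there
    is a single sub-trial (the reference) with delta_u_amp_uV exactly 0.
    """
    p = params or ExtractParams()
    groups = partition_groups(beats)
    lead = record if record.n_leads == 1 else None
    if lead is None:
        from .io_ecg import select_lead
        lead = select_lead(record, list(p.lead_preference))
    # extract the 100 reference windows once; sub-trials index into them
    ref_beats = QualifyingBeats(
        np.concatenate(groups), beats.fs, beats.window_pre_ms,
        beats.window_post_ms, beats.criteria,
    )
    segments, time_ms = extract_beat_windows(lead, ref_beats)
    if segments.shape[0] != N_GROUPS * GROUP_SIZE:
        raise InsufficientBeatsError("reference windows incomplete after extraction")
    seg_groups = segments.reshape(N_GROUPS, GROUP_SIZE, -1)

    def measure(seg):
        avg = compute_average_beat(seg, time_ms, lead.fs)
        return avg, umeasure.measure_u_wave(
            avg, mode=mode,
            qrs_onset_offset_ms=p.qrs_onset_offset_ms,
            p_onset_offset_ms=p.p_onset_offset_ms,
            search_window_ms=tuple(p.u_search_ms),
            noise_floor_uV=p.u_noise_floor_uV,
        )

    _, ref = measure(segments)
    rows = []
    for n in sorted(n_beats_grid, reverse=True):
        subtrials = [1] if n == N_GROUPS * GROUP_SIZE else range(1, N_GROUPS + 1)
        for s in subtrials:
            gs = subtrial_groups(n, s)
            seg = seg_groups[list(gs)].reshape(-1, seg_groups.shape[-1])
            _, m = measure(seg)
            rows.append({
                "record_id": record.record_id,
                "n_beats": n,
                "subtrial": s,
                "groups_used": ",".join(str(g + 1) for g in gs),
                "n_segments": seg.shape[0],
                "u_amp_uV": m.u_amp_uV,
                "delta_u_amp_uV": m.u_amp_uV - ref.u_amp_uV,
                "baseline_uV": m.baseline_uV,
                "u_peak_time_ms": m.u_peak_time_ms,
            })
    return pd.DataFrame(rows)


@dataclass
class NBeatsSummary:
    per_n: pd.DataFrame            # per-N mean/sd of delta_u_amp across records
    anova_p: float                 # within-subject ANOVA across N levels
    anova_degenerate: bool
    posthoc: pd.DataFrame          # per-N paired t vs zero
    n_records: int


def summarize_nbeats(results: pd.DataFrame, alpha: float = 0.05) -> NBeatsSummary:
    """Cohort summary of sub-trial results (long DataFrame from
    :func:`run_subtrials`, concatenated across records).

    Per record and N, sub-trial amplitudes are first averaged; the summary
    then reports the across-record mean and s.d. of delta_u_amp (and its
    percentage of the reference amplitude), a one-way repeated-measures
    ANOVA across the reduced-N levels, and per-N two-sided one-sample
    t-tests of delta_u_amp against zero. Records with incomplete grids are
    excluded with a warning; zero-variance (e.g. noiseless) inputs yield a
    degenerate-flagged ANOVA and p = 1 post-hocs by convention.
    """
    from scipy import stats as sps

    full_grid = set(NBEATS_GRID)
    keep = []
    for rid, df in results.groupby("record_id"):
        if set(df["n_beats"].unique()) >= full_grid:
            keep.append(rid)
        else:
            log.warning("record %s has an incomplete n-beats grid; excluded", rid)
    results = results[results["record_id"].isin(keep)]
    n_records = len(keep)
    if n_records < 2:
        raise ValueError("summarize_nbeats needs at least 2 records with complete grids")

    per_rec = (
        results.groupby(["record_id", "n_beats"], as_index=False)
        .agg(delta_u_amp_uV=("delta_u_amp_uV", "mean"), u_amp_uV=("u_amp_uV", "mean"))
    )
    ref = results[results["n_beats"] == 100].groupby("record_id")["u_amp_uV"].mean()
    per_rec["pct_of_ref"] = per_rec.apply(
        lambda r: 100.0 * r["delta_u_amp_uV"] / ref[r["record_id"]], axis=1
    )
    per_n = (
        per_rec.groupby("n_beats")
        .agg(
            mean_delta_uV=("delta_u_amp_uV", "mean"),
            sd_delta_uV=("delta_u_amp_uV", "std"),
            mean_pct=("pct_of_ref", "mean"),
            mean_u_amp_uV=("u_amp_uV", "mean"),
        )
        .reset_index()
        .sort_values("n_beats", ascending=False, ignore_index=True)
    )

    reduced = per_rec[per_rec["n_beats"] < 100]
    pivot = reduced.pivot(index="record_id", columns="n_beats", values="delta_u_amp_uV")
    anova_p, degenerate = np.nan, False
    if np.allclose(pivot.to_numpy().std(), 0):
        degenerate = True
        anova_p = 1.0
    else:
        try:
            from statsmodels.stats.anova import AnovaRM

            long = reduced.rename(columns={"delta_u_amp_uV": "delta"})
            res = AnovaRM(long, depvar="delta", subject="record_id",
                          within=["n_beats"]).fit()
            anova_p = float(res.anova_table["Pr > F"].iloc[0])
        except Exception as exc:  # zero residual variance and similar
            log.warning("repeated-measures ANOVA degenerate: %s", exc)
            degenerate = True
            anova_p = 1.0

    ph_rows = []
    for n, grp in reduced.groupby("n_beats"):
        d = grp["delta_u_amp_uV"].to_numpy()
        if np.allclose(d.std(), 0):
            p = 1.0 if np.allclose(d, 0) else 0.0
            t = np.inf if p == 0.0 else 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = sps.ttest_1samp(d, 0.0)
        ph_rows.append({"n_beats": n, "mean_delta_uV": d.mean(), "t": float(t),
                        "p_value": float(p), "significant": bool(p < alpha)})
    posthoc = pd.DataFrame(ph_rows).sort_values("n_beats", ascending=False,
                                                ignore_index=True)
    return NBeatsSummary(per_n, float(anova_p), degenerate, posthoc, n_records)
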