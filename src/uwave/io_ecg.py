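"""ECG record I/O.

Reads PhysioNet-style WFDB records (.hea/.dat, formats 16 and 212) and a
simple CSV dialect (header row of lead names, one sample per row, sampling
rate and units in a YAML sidecar), normalising everything into
:class:`ECGRecord` with amplitudes in microvolts.

Conventions used throughout the package: amplitudes in uV, times in ms,
sample indices 0-based.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

RHYTHMS = ("AF", "SR", "unknown")


class ConfigurationError(ValueError):
    """A required configuration value is missing or inconsistent."""


class RecordValidationError(ValueError):
    """Waveform data violates an ECGRecord invariant."""


@dataclass
class ECGRecord:
    """A sampled multi-lead ECG.

    Parameters
    ----------
    samples : ndarray, shape (n_leads, n_samples)
        Per-lead amplitude series in microvolts.
    fs : float
        Sampling rate in Hz.
    lead_names : list of str
        Ordered, unique lead labels, one per row of ``samples``.
    rhythm : {"AF", "SR", "unknown"}
        Rhythm tag; drives mode-dependent analysis defaults.
    record_id : str
        Free-text identifier.
    """

    samples: np.ndarray
    fs: float
    lead_names: list[str]
    rhythm: str = "unknown"
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise RecordValidationError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[1] < 1:
            raise RecordValidationError("record must contain at least one sample")
        if len(self.lead_names) != self.samples.shape[0]:
            raise RecordValidationError(
                f"{len(self.lead_names)} lead names for {self.samples.shape[0]} leads"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise RecordValidationError(f"duplicate lead names: {self.lead_names}")
        if self.rhythm not in RHYTHMS:
            raise RecordValidationError(f"rhythm must be one of {RHYTHMS}")
        bad = ~np.isfinite(self.samples)
        if bad.any():
            lead_i, idx = np.argwhere(bad)[0]
            raise RecordValidationError(
                f"non-finite sample in lead {self.lead_names[lead_i]!r} at index {idx}"
            )

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.samples[self.lead_names.index(name)]


def select_lead(record: ECGRecord, preference: list[str]) -> ECGRecord:
    """Return a single-lead record following an ordered lead preference.

    The first preferred label present in the record wins (the lead with the
    most prominent U wave, conventionally V4, is preferred for U-wave work).
    If none of the preferred leads is present the first lead is used and the
    fallback is logged.
    """
    if record.n_leads > 1 and not preference:
        raise ConfigurationError("lead preference required for a multi-lead record")
    chosen = None
    for name in preference:
        if name in record.lead_names:
            chosen = name
            break
    if chosen is None:
        chosen = record.lead_names[0]
        if record.n_leads > 1 or preference:
            log.warning(
                "none of preferred leads %s present in %s; falling back to %r",
                preference, record.record_id or "<record>", chosen,
            )
    return replace(
        record,
        samples=record.lead(chosen)[np.newaxis, :].copy(),
        lead_names=[chosen],
    )


# ---------------------------------------------------------------------------
# WFDB (.hea / .dat), formats 16 and 212

@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float          # adu per physical unit (mV unless stated)
    baseline: int
    adc_zero: int
    units: str
    description: str


def _parse_header(hea_path: Path):
    lines = [
        ln.strip() for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    specs: list[_SignalSpec] = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fname = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(specs)}"
        specs.append(_SignalSpec(fname, fmt, gain, baseline, adc_zero, units, desc))
    return name, n_sig, fs, n_samples, specs


def _read_dat(path: Path, fmt: int, n_sig: int, n_samples: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")
        if n_samples:
            adc = adc[: n_sig * n_samples]
        adc = adc.reshape(-1, n_sig).T.astype(np.int64)
    elif fmt == 212:
        # 2 samples packed into 3 bytes, 12-bit two's complement
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: 3 * (len(b) // 3)].reshape(-1, 3).astype(np.int64)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        flat = np.empty(2 * len(b), dtype=np.int64)
        flat[0::2], flat[1::2] = s0, s1
        flat[flat > 2047] -= 4096
        if n_samples:
            flat = flat[: n_sig * n_samples]
        adc = flat.reshape(-1, n_sig).T
    else:
        raise NotImplementedError(f"WFDB signal format {fmt} not supported (16, 212 are)")
    return adc


def read_wfdb(path: str | Path, gain_to_uV: float = 1000.0) -> ECGRecord:
    """Read a WFDB record given its .hea path (or header-less base path).

    Digital values are converted to physical units via each signal's gain
    and baseline (``(adu - baseline) / gain``, conventionally mV), then
    scaled by ``gain_to_uV`` (uV per physical unit; 1000 for mV signals).
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    name, n_sig, fs, n_samples, specs = _parse_header(hea)
    by_file: dict[str, list[int]] = {}
    for i, sp in enumerate(specs):
        by_file.setdefault(sp.file_name, []).append(i)
    leads = [None] * n_sig
    for fname, idxs in by_file.items():
        dat = hea.parent / fname
        if not dat.exists():
            raise FileNotFoundError(f"WFDB signal file not found: {dat}")
        fmt = specs[idxs[0]].fmt
        adc = _read_dat(dat, fmt, len(idxs), n_samples)
        for j, i in enumerate(idxs):
            sp = specs[i]
            leads[i] = (adc[j] - sp.baseline) / sp.gain * gain_to_uV
    names, seen = [], set()
    for i, sp in enumerate(specs):
        nm = sp.description or f"sig{i}"
        while nm in seen:
            nm += "_"
        seen.add(nm)
        names.append(nm)
    return ECGRecord(np.vstack(leads), fs, names, rhythm="unknown", record_id=name)


def write_wfdb(record: ECGRecord, base_path: str | Path, gain: float = 200.0) -> Path:
    """Write a record as a format-16 WFDB pair; returns the .hea path.

    Amplitudes (uV) are stored as ``round(uV / 1000 * gain)`` adu, i.e. the
    on-disk physical unit is mV.
    """
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    adc = np.round(record.samples / 1000.0 * gain).astype("<i2")
    dat_name = base.name + ".dat"
    (base.parent / dat_name).write_bytes(adc.T.tobytes())
    lines = [f"{base.name} {record.n_leads} {record.fs:g} {record.n_samples}"]
    for nm, row in zip(record.lead_names, adc):
        first = int(row[0])
        cksum = int(np.sum(row, dtype=np.int64) % 65536)
        if cksum > 32767:
            cksum -= 65536
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 12 0 {first} {cksum} 0 {nm}")
    lines.append(f"# rhythm: {record.rhythm}")
    hea = base.with_suffix(".hea")
    hea.write_text("\n".join(lines) + "\n")
    return hea


# ---------------------------------------------------------------------------
# CSV + YAML sidecar

def sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".yaml")


def read_csv(path: str | Path, gain_to_uV: float = 1.0) -> ECGRecord:
    """Read the CSV dialect: header row of lead names, one sample per row.

    A YAML sidecar (same stem, ``.yaml``) must supply ``fs`` and may supply
    ``rhythm``, ``record_id`` and ``gain_to_uV`` (overridden by the argument
    when it differs from 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CSV record not found: {path}")
    sc = sidecar_path(path)
    meta = {}
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    if "fs" not in meta:
        raise ConfigurationError(
            f"sampling rate missing: CSV records need 'fs' in sidecar {sc}"
        )
    if gain_to_uV == 1.0:
        gain_to_uV = float(meta.get("gain_to_uV", 1.0))
    df = pd.read_csv(path)
    return ECGRecord(
        samples=df.to_numpy(dtype=float).T * gain_to_uV,
        fs=float(meta["fs"]),
        lead_names=[str(c) for c in df.columns],
        rhythm=str(meta.get("rhythm", "unknown")),
        record_id=str(meta.get("record_id", path.stem)),
    )


def write_csv(record: ECGRecord, path: str | Path, float_fmt: str = "%.3f") -> Path:
    """Write a record as CSV (uV, 3 decimals by default) plus YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(record.samples.T, columns=record.lead_names)
    df.to_csv(path, index=False, float_format=float_fmt)
    sidecar_path(path).write_text(
        yaml.safe_dump(
            {
                "fs": record.fs,
                "rhythm": record.rhythm,
                "record_id": record.record_id,
                "units": "uV",
                "gain_to_uV": 1.0,
            },
            sort_keys=False,
        )
    )
    return path


def read_record(path: str | Path, format: str = "auto", gain_to_uV: float | None = None) -> ECGRecord:
    """Read an ECG record in WFDB or CSV format, amplitudes in uV.

    ``format="auto"`` dispatches on the file extension (.hea -> WFDB,
    .csv -> CSV). ``gain_to_uV`` defaults to 1000 for WFDB (mV physical
    units) and 1 for CSV (sidecar may override).
    """
    path = Path(path)
    if format == "auto":
        format = {".hea": "wfdb", ".dat": "wfdb", ".csv": "csv"}.get(path.suffix, "")
        if not format:
            raise ConfigurationError(f"cannot infer record format from {path.name!r}")
    if format == "wfdb":
        return read_wfdb(path, gain_to_uV if gain_to_uV is not None else 1000.0)
    if format == "csv":
        return read_csv(path, gain_to_uV if gain_to_uV is not None else 1.0)
    raise ConfigurationError(f"unknown record format {format!r}")


def resample_record(record: ECGRecord, fs_new: float) -> ECGRecord:
    """Optional polyphase resampling (off the default path; analysis runs at
    native fs)."""
    from fractions import Fraction

    from scipy.signal import resample_poly

    frac = Fraction(fs_new / record.fs).limit_denominator(1000)
    out = np.vstack(
        [resample_poly(row, frac.numerator, frac.denominator) for row in record.samples]
    )
    return replace(record, samples=out, fs=record.fs * frac.numerator / frac.denominator)
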