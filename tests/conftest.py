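import numpy as np
import pytest

from uwave.pipeline import ExtractParams, extract_u_wave, prepare_beats
from uwave.synth import SynthConfig, simulate_record


@pytest.fixture(scope="session")
def af_config():
    return SynthConfig(duration_s=420.0)


@pytest.fixture(scope="session")
def af_record(af_config):
    """Standard AF study record: 7 min at 500 Hz, defaults."""
    return simulate_record(af_config, seed=1)


@pytest.fixture(scope="session")
def af_extraction(af_record):
    rec, _ = af_record
    return extract_u_wave(rec, ExtractParams(max_beats=100))


@pytest.fixture(scope="session")
def noiseless_config():
    """Regular 800 ms RR, no f-wave, no noise: every beat is identical."""
    return SynthConfig(duration_s=120.0, rr_mean_ms=800.0, rr_sd_ms=0.0,
                       f_amp_uV=0.0, white_sd_uV=0.0, powerline_amp_uV=0.0)


@pytest.fixture(scope="session")
def noiseless_record(noiseless_config):
    return simulate_record(noiseless_config, seed=0)


@pytest.fixture(scope="session")
def sr_record():
    return simulate_record(SynthConfig(duration_s=240.0).sr_defaults(), seed=3)


def rr_to_peaks(rr_ms, fs=500.0, pad_samples=2000):
    """Build an RPeakSeries from an RR list (ms); first R at pad_samples."""
    from uwave.rpeaks import RPeakSeries

    idx = pad_samples + np.round(
        np.concatenate(([0.0], np.cumsum(rr_ms))) / 1000.0 * fs
    ).astype(np.int64)
    return RPeakSeries(idx, fs, int(idx[-1] + pad_samples))
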