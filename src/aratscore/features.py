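"""Fixed 74-feature representation of a task segment.

60 time-domain features — ten descriptive statistics per each of the six
channels (world-frame linear acceleration x/y/z, sensor-frame angular
velocity x/y/z) — plus 14 frequency-domain features, seven per vector
norm (acceleration norm and angular-velocity norm): peak frequency, five
band energies partitioning 0-25 Hz, and the spectral centroid.

Conventions pinned here for reproducibility: minimum/maximum are the 5th
and 95th percentiles (linear-interpolation quantiles), range is their
difference; zero-crossing rate counts strict sign changes of the
mean-removed channel per transition; kurtosis is Fisher (excess) and 0
for constant channels; spectra are single un-windowed FFTs of the
mean-removed norm with energies normalised by sequence length, and the
DC bin is excluded from the peak-frequency search.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import TaskSegment

CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")
TIME_STATS = (
    "mean",
    "std",
    "min_p5",
    "max_p95",
    "range",
    "mad",
    "iqr",
    "upper_quartile",
    "zcr",
    "kurtosis",
)
NORMS = ("acc_norm", "gyr_norm")
FREQ_STATS = (
    "max_freq_component",
    "band_energy_0_5",
    "band_energy_5_10",
    "band_energy_10_15",
    "band_energy_15_20",
    "band_energy_20_25",
    "spectral_centroid",
)
BAND_EDGES_HZ = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)
MAX_FREQ_HZ = 25.0  # Nyquist at 50 Hz

TIME_FEATURE_COLUMNS = [f"{ch}_{st}" for ch in CHANNELS for st in TIME_STATS]
FREQ_FEATURE_COLUMNS = [f"{nm}_{st}" for nm in NORMS for st in FREQ_STATS]
#: the fixed, documented column order of the 74 features
FEATURE_COLUMNS = TIME_FEATURE_COLUMNS + FREQ_FEATURE_COLUMNS

METADATA_COLUMNS = ["subject", "session", "arm", "domain", "task", "score", "substituted"]

MIN_FREQ_SAMPLES = 50  # 1 s at 50 Hz


def _channel_stats(x: np.ndarray) -> dict[str, float]:
    p5, p25, p75, p95 = np.percentile(x, [5, 25, 75, 95])
    centered = x - x.mean()
    signs = np.sign(centered)
    nz = signs[signs != 0]
    crossings = int(np.count_nonzero(np.diff(nz) != 0)) if nz.size > 1 else 0
    n = x.size
    if np.ptp(x) == 0:
        kurt = 0.0
    else:
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return {
        "mean": float(x.mean()),
        "std": float(x.std(ddof=0)),
        "min_p5": float(p5),
        "max_p95": float(p95),
        "range": float(p95 - p5),
        "mad": float(np.mean(np.abs(centered))),
        "iqr": float(p75 - p25),
        "upper_quartile": float(p75),
        "zcr": crossings / (n - 1) if n > 1 else 0.0,
        "kurtosis": kurt,
    }


def extract_time_features(segment: TaskSegment) -> dict[str, float]:
    """Ten descriptive statistics for each of the six channels (60 values)."""
    if segment.n_samples == 0:
        raise ValueError("segment is empty")
    out: dict[str, float] = {}
    channels = segment.channels
    for j, ch in enumerate(CHANNELS):
        for st, v in _channel_stats(channels[:, j]).items():
            out[f"{ch}_{st}"] = v
    return out


def _spectrum_stats(signal: np.ndarray, fs: float) -> dict[str, float]:
    n = signal.size
    x = signal - signal.mean()
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    out: dict[str, float] = {}
    # peak frequency, DC excluded
    k = 1 + int(np.argmax(mag[1:]))
    out["max_freq_component"] = float(freqs[k])
    power = mag**2 / n
    for lo, hi in zip(BAND_EDGES_HZ[:-1], BAND_EDGES_HZ[1:]):
        if hi >= MAX_FREQ_HZ:  # last band closed at Nyquist
            band = (freqs >= lo) & (freqs <= hi)
        else:
            band = (freqs >= lo) & (freqs < hi)
        out[f"band_energy_{int(lo)}_{int(hi)}"] = float(power[band].sum())
    in_range = freqs <= MAX_FREQ_HZ
    denom = float(mag[in_range].sum())
    if denom > 0:
        out["spectral_centroid"] = float(
            (freqs[in_range] * mag[in_range]).sum() / denom
        )
    else:
        out["spectral_centroid"] = 0.0
    return out


def extract_frequency_features(segment: TaskSegment) -> dict[str, float]:
    """Seven spectral statistics per vector norm (14 values).

    Requires at least one second of data (50 samples).
    """
    if segment.n_samples < MIN_FREQ_SAMPLES:
        raise ValueError("segment shorter than 1 s; cannot compute spectra")
    fs = segment.sampling_hz
    norms = {
        "acc_norm": np.linalg.norm(segment.linear_accel, axis=1),
        "gyr_norm": np.linalg.norm(segment.gyro, axis=1),
    }
    out: dict[str, float] = {}
    for nm, sig in norms.items():
        for st, v in _spectrum_stats(sig, fs).items():
            out[f"{nm}_{st}"] = v
    return out


def extract_features(segment: TaskSegment) -> dict[str, float]:
    """All 74 features of one segment, in the documented column order."""
    vals = {**extract_time_features(segment), **extract_frequency_features(segment)}
    return {c: vals[c] for c in FEATURE_COLUMNS}


def build_feature_table(segments: list[TaskSegment]) -> pd.DataFrame:
    """One row per segment: metadata columns followed by the 74 features.

    Raises on duplicate (subject, session, arm, task) keys.
    """
    if not segments:
        raise ValueError("no segments given")
    seen: set[tuple] = set()
    rows = []
    for seg in segments:
        key = (seg.subject, seg.session, seg.arm, seg.task)
        if key in seen:
            raise ValueError(f"duplicate segment key {key}")
        seen.add(key)
        row: dict = {
            "subject": seg.subject,
            "session": seg.session,
            "arm": seg.arm,
            "domain": seg.domain,
            "task": seg.task,
            "score": seg.score,
            "substituted": seg.substituted,
        }
        row.update(extract_features(seg))
        rows.append(row)
    return pd.DataFrame(rows, columns=METADATA_COLUMNS + FEATURE_COLUMNS)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV with full float precision, so a
    write/read round trip reproduces values bit-identically."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    # round_trip parsing: the default float parser loses the last ulp
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing[:3]}...")
    return table
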