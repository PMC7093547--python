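"""Channel cleaning and the minimum-duration gate.

Oximetry: samples under 50% saturation are physiologically implausible
at the finger probe and are removed together with transient deep spikes
caused by movement (detected by implausible 1-s slopes); the signal is
then anti-alias filtered and downsampled to 3 Hz, the conventional
analysis rate for overnight oximetry.

Airflow: sustained sensor malfunction (flatline or rail saturation) is
invalidated, a zero-phase 1.2 Hz low-pass removes cardiogenic and
instrumentation noise, and the signal is decimated to a 5 Hz analysis
rate (comfortably above twice the filter cut-off).

Recordings retaining less than four hours of valid signal on either
channel after cleaning are rejected as insufficient for AHI estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .signals import AirflowSignal, OximetrySignal, Recording

__all__ = [
    "PreprocessReport",
    "clean_spo2",
    "clean_airflow",
    "validate_duration",
    "preprocess_recording",
    "SPO2_ANALYSIS_FS",
    "AIRFLOW_ANALYSIS_FS",
    "MIN_VALID_HOURS",
]

SPO2_ANALYSIS_FS = 3.0
AIRFLOW_ANALYSIS_FS = 5.0
MIN_VALID_HOURS = 4.0

#: SpO2 slopes steeper than this (%/s on a 1-s average) flag probe artefact
TRANSIENT_SLOPE_PCT_PER_S = 4.0
#: a fall/recovery pair closer than this is treated as one transient dip
MAX_TRANSIENT_S = 30.0

#: airflow flatline rule: >= this long with almost no local variance
FLATLINE_MIN_S = 30.0
FLATLINE_SD_WINDOW_S = 10.0
FLATLINE_SD_FRACTION = 0.01
#: rail-saturation rule: pinned at the extreme value at least this long
RAIL_MIN_S = 5.0

LOWPASS_CUTOFF_HZ = 1.2
LOWPASS_ORDER = 4


@dataclass
class PreprocessReport:
    """Bookkeeping for one recording's cleaning pass."""

    removed_spo2_samples: int = 0
    removed_airflow_seconds: float = 0.0
    post_duration_h: dict = field(default_factory=dict)
    accepted: bool | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``mask`` is True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def _interpolate_invalid(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation across invalid stretches (for filtering only)."""
    if valid.all():
        return x
    if not valid.any():
        raise ValueError("signal has no valid samples")
    out = x.copy()
    idx = np.arange(x.size)
    out[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return out


def _resample(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    ratio = Fraction(target_fs / fs).limit_denominator(1000)
    # linear edge extension: zero padding would inject huge edge
    # transients into signals with a large DC offset (SpO2 sits near 95)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator, padtype="line")


def _downsample_mask(valid: np.ndarray, fs: float, target_fs: float, n_out: int) -> np.ndarray:
    """A low-rate sample is valid iff every native sample it covers was."""
    t_out = np.arange(n_out) / target_fs
    half = 0.5 * fs / target_fs
    centre = t_out * fs
    out = np.empty(n_out, dtype=bool)
    lo = np.clip(np.floor(centre - half).astype(int), 0, valid.size)
    hi = np.clip(np.ceil(centre + half).astype(int) + 1, 0, valid.size)
    cum = np.concatenate(([0], np.cumsum(~valid)))
    out[:] = (cum[hi] - cum[lo]) == 0
    return out


def _transient_deep_mask(x: np.ndarray, fs: float) -> np.ndarray:
    """True where the transient-dip rule invalidates samples.

    A 1-s moving average falling faster than 4%/s marks a dip onset; the
    next equally steep recovery within 30 s closes it; the enclosed
    interval (plus the steep samples) is invalidated.
    """
    win = max(int(round(fs)), 1)
    smooth = uniform_filter1d(x, size=win, mode="nearest")
    slope = np.gradient(smooth) * fs  # %/s
    falling = slope < -TRANSIENT_SLOPE_PCT_PER_S
    rising = slope > TRANSIENT_SLOPE_PCT_PER_S
    bad = falling | rising
    max_gap = int(round(MAX_TRANSIENT_S * fs))
    rise_idx = np.flatnonzero(rising)
    for start, stop in _runs(falling):
        pos = np.searchsorted(rise_idx, stop)
        if pos < rise_idx.size and rise_idx[pos] - stop <= max_gap:
            bad[stop : rise_idx[pos]] = True
    return bad


def clean_spo2(
    raw: OximetrySignal, target_fs: float = SPO2_ANALYSIS_FS
) -> tuple[OximetrySignal, PreprocessReport]:
    """Clean an oximetry channel and bring it to the 3 Hz analysis rate."""
    if raw.samples.size == 0:
        raise ValueError("empty SpO2 signal")
    if raw.fs < target_fs:
        raise ValueError(f"SpO2 sampling rate {raw.fs} Hz below analysis rate")
    x = raw.samples
    valid = raw.valid_mask.copy()
    valid &= np.isfinite(x)
    valid &= (x >= 50.0) & (x <= 100.0)
    valid &= ~_transient_deep_mask(np.where(np.isfinite(x), x, 100.0), raw.fs)
    removed = int(np.count_nonzero(raw.valid_mask) - np.count_nonzero(valid))

    filled = _interpolate_invalid(x, valid)
    if raw.fs == target_fs:
        y, mask = filled, valid
    else:
        y = _resample(filled, raw.fs, target_fs)
        mask = _downsample_mask(valid, raw.fs, target_fs, y.size)
    y = np.clip(y, 50.0, 100.0)
    out = OximetrySignal(samples=y, fs=target_fs, t0=raw.t0, valid_mask=mask, processed=True)
    report = PreprocessReport(
        removed_spo2_samples=removed,
        post_duration_h={"spo2": out.valid_seconds / 3600.0},
    )
    return out, report


def _malfunction_mask(x: np.ndarray, fs: float) -> np.ndarray:
    """Flatline and rail-saturation segments of an airflow trace."""
    bad = np.zeros(x.size, dtype=bool)
    global_sd = float(np.std(x))
    if global_sd > 0:
        win = max(int(round(FLATLINE_SD_WINDOW_S * fs)), 2)
        mean = uniform_filter1d(x, size=win, mode="nearest")
        meansq = uniform_filter1d(x * x, size=win, mode="nearest")
        local_sd = np.sqrt(np.maximum(meansq - mean * mean, 0.0))
        flat = local_sd < FLATLINE_SD_FRACTION * global_sd
        min_len = int(round(FLATLINE_MIN_S * fs))
        for start, stop in _runs(flat):
            if stop - start >= min_len:
                bad[start:stop] = True
    # rail saturation: pinned exactly at the record extremes
    for rail in (np.max(x), np.min(x)):
        pinned = x == rail
        min_len = int(round(RAIL_MIN_S * fs))
        for start, stop in _runs(pinned):
            if stop - start >= min_len:
                bad[start:stop] = True
    return bad


def clean_airflow(
    raw: AirflowSignal, target_fs: float | None = AIRFLOW_ANALYSIS_FS
) -> tuple[AirflowSignal, PreprocessReport]:
    """Clean an airflow channel: malfunction removal, 1.2 Hz low-pass, decimation."""
    if raw.samples.size == 0:
        raise ValueError("empty airflow signal")
    if raw.fs <= 2 * LOWPASS_CUTOFF_HZ:
        raise ValueError(f"airflow sampling rate {raw.fs} Hz too low for 1.2 Hz low-pass")
    x = np.where(np.isfinite(raw.samples), raw.samples, 0.0)
    valid = raw.valid_mask.copy()
    valid &= np.isfinite(raw.samples)
    valid &= ~_malfunction_mask(x, raw.fs)
    removed_s = (np.count_nonzero(raw.valid_mask) - np.count_nonzero(valid)) / raw.fs

    filled = _interpolate_invalid(x, valid) if valid.any() else x
    if not raw.processed:
        sos = sps.butter(LOWPASS_ORDER, LOWPASS_CUTOFF_HZ, btype="low", fs=raw.fs, output="sos")
        filled = sps.sosfiltfilt(sos, filled)
    if target_fs is None or target_fs == raw.fs:
        y, mask, out_fs = filled, valid, raw.fs
    else:
        y = _resample(filled, raw.fs, target_fs)
        mask = _downsample_mask(valid, raw.fs, target_fs, y.size)
        out_fs = target_fs
    out = AirflowSignal(samples=y, fs=out_fs, t0=raw.t0, valid_mask=mask, processed=True)
    report = PreprocessReport(
        removed_airflow_seconds=float(removed_s),
        post_duration_h={"airflow": out.valid_seconds / 3600.0},
    )
    return out, report


def validate_duration(
    spo2: OximetrySignal, airflow: AirflowSignal, min_hours: float = MIN_VALID_HOURS
) -> bool:
    """Accept a cleaned recording iff both channels keep >= ``min_hours`` valid."""
    return (
        spo2.valid_seconds >= min_hours * 3600.0
        and airflow.valid_seconds >= min_hours * 3600.0
    )


def preprocess_recording(
    rec: Recording, min_hours: float = MIN_VALID_HOURS
) -> tuple[Recording, PreprocessReport]:
    """Clean both channels of a recording and apply the duration gate."""
    spo2, rep_s = clean_spo2(rec.spo2)
    airflow, rep_a = clean_airflow(rec.airflow)
    report = PreprocessReport(
        removed_spo2_samples=rep_s.removed_spo2_samples,
        removed_airflow_seconds=rep_a.removed_airflow_seconds,
        post_duration_h={**rep_s.post_duration_h, **rep_a.post_duration_h},
        accepted=validate_duration(spo2, airflow, min_hours),
    )
    cleaned = Recording(
        id=rec.id,
        spo2=spo2,
        airflow=airflow,
        reference_ahi=rec.reference_ahi,
        trt_seconds=rec.trt_seconds,
    )
    return cleaned, report
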