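"""Spectral characterisation of SpO2 and airflow recordings.

Recurrent respiratory events imprint quasi-periodic oscillations on both
channels.  Their power concentrates in narrow, signal-specific bands:
roughly 0.014–0.033 Hz for oximetry (desaturation/resaturation cycles)
and 0.025–0.050 Hz for airflow.  The power spectral density (PSD) is
estimated by Welch's method and summarised inside the band of interest
by amplitude moments, Shannon spectral entropy, median frequency,
Wootters statistical distance to the uniform spectrum, amplitude
extrema and relative power.

Resolving a band ~20 mHz wide requires a frequency step well under
1 mHz, hence the heavy FFT zero-padding used by :func:`estimate_psd`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._stats import four_moments

__all__ = [
    "SpectralBand",
    "SPO2_BAND",
    "AIRFLOW_BAND",
    "PSDEstimate",
    "estimate_psd",
    "band_stats",
    "spectral_entropy",
    "median_frequency",
    "wootters_distance",
]


@dataclass(frozen=True)
class SpectralBand:
    """A frequency interval [lo_hz, hi_hz] of interest."""

    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError(f"need 0 < lo < hi, got [{self.lo_hz}, {self.hi_hz}]")


#: OSA-related band for oximetry (desaturation cycling).
SPO2_BAND = SpectralBand(0.014, 0.033)
#: OSA-related band for nasal-pressure airflow (event cycling).
AIRFLOW_BAND = SpectralBand(0.025, 0.050)


@dataclass
class PSDEstimate:
    """A one-sided Welch PSD on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    df: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(self.power < 0):
            raise ValueError("PSD values must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def band_slice(self, band: SpectralBand) -> slice:
        """Index slice covering ``band`` (inclusive of both edges)."""
        lo = int(np.searchsorted(self.freqs, band.lo_hz, side="left"))
        hi = int(np.searchsorted(self.freqs, band.hi_hz, side="right"))
        if hi - lo < 1:
            raise ValueError(
                f"band [{band.lo_hz}, {band.hi_hz}] Hz not resolved at df={self.df}"
            )
        return slice(lo, hi)

    def band_power(self, psd_slice: slice | None = None) -> float:
        p = self.power if psd_slice is None else self.power[psd_slice]
        return float(np.sum(p) * self.df)

    def total_power_no_dc(self) -> float:
        """Total power excluding the DC bin (denominator of relative power)."""
        start = 1 if self.freqs[0] == 0.0 else 0
        return float(np.sum(self.power[start:]) * self.df)


# Welch defaults: long 512-s segments with a Hann window and 50% overlap
# give enough averaging on a full night while the zero-padded FFT keeps
# the grid finer than 1 mHz.
SEGMENT_SECONDS = 512.0
TARGET_DF_HZ = 1e-3


def estimate_psd(
    x: np.ndarray,
    fs: float,
    segment_seconds: float = SEGMENT_SECONDS,
    target_df_hz: float = TARGET_DF_HZ,
) -> PSDEstimate:
    """Welch PSD of a cleaned, uniformly sampled series.

    The segment length is capped at the signal length; the FFT length is
    zero-padded to the next power of two achieving ``df <= target_df_hz``
    (or at least the segment length for short inputs).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("signal too short for a PSD estimate")
    nperseg = min(x.size, int(round(segment_seconds * fs)))
    nfft = int(2 ** np.ceil(np.log2(max(nperseg, fs / target_df_hz))))
    freqs, power = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=nfft,
        detrend="constant",
        scaling="density",
    )
    return PSDEstimate(freqs=freqs, power=power, df=float(freqs[1] - freqs[0]))


def _band_amplitudes(psd: PSDEstimate, band: SpectralBand) -> np.ndarray:
    return psd.power[psd.band_slice(band)]


def band_stats(psd: PSDEstimate, band: SpectralBand) -> dict[str, float]:
    """Moments and amplitude/power summaries of the in-band PSD.

    Returns M1f–M4f (mean, unbiased variance, skewness, kurtosis of the
    in-band spectral amplitudes), MA/mA (max/min amplitude) and PR
    (in-band power over total power excluding DC).
    """
    amps = _band_amplitudes(psd, band)
    if amps.size < 8:
        raise ValueError("band too narrow at this resolution (<8 bins)")
    m1, m2, m3, m4, _ = four_moments(amps)
    total = psd.total_power_no_dc()
    pr = float(np.sum(amps) * psd.df / total) if total > 0 else 0.0
    return {
        "M1f": m1,
        "M2f": m2,
        "M3f": m3,
        "M4f": m4,
        "MA": float(np.max(amps)),
        "mA": float(np.min(amps)),
        "PR": min(pr, 1.0),
    }


def _band_probabilities(psd: PSDEstimate, band: SpectralBand) -> np.ndarray:
    amps = _band_amplitudes(psd, band)
    if amps.size < 2:
        raise ValueError("need at least 2 in-band bins")
    total = amps.sum()
    if total <= 0:
        raise ValueError("zero in-band power")
    return amps / total


def spectral_entropy(psd: PSDEstimate, band: SpectralBand) -> float:
    """Normalised Shannon entropy of the in-band spectrum, in [0, 1].

    1 for a flat in-band spectrum, 0 when all power sits in one bin.
    """
    p = _band_probabilities(psd, band)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)) / np.log(p.size))


def median_frequency(psd: PSDEstimate, band: SpectralBand) -> float:
    """Smallest in-band frequency at which cumulative power reaches 50%."""
    sl = psd.band_slice(band)
    amps = psd.power[sl]
    total = amps.sum()
    if total <= 0:
        raise ValueError("zero in-band power")
    csum = np.cumsum(amps)
    idx = int(np.searchsorted(csum, 0.5 * total))
    return float(psd.freqs[sl][idx])


def wootters_distance(psd: PSDEstimate, band: SpectralBand) -> float:
    """Wootters statistical distance between the in-band spectrum and uniform.

    ``WD = arccos(sum_i sqrt(p_i * u_i))`` with ``u`` uniform over the
    in-band bins; 0 for a flat spectrum, approaching ``arccos(1/sqrt(N))``
    for a single spectral line.
    """
    p = _band_probabilities(psd, band)
    u = 1.0 / p.size
    overlap = float(np.sum(np.sqrt(p * u)))
    return float(np.arccos(np.clip(overlap, -1.0, 1.0)))
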