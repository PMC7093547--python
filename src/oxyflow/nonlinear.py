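"""Non-linear series descriptors: sample entropy, CTM and Lempel–Ziv complexity.

These three measures summarise the irregularity, variability and
structural complexity of overnight SpO2/airflow traces.  Repetitive
respiratory events make the signals more structured (lower entropy and
complexity, first-difference scatter spreading with event severity), so
all three carry OSA-related information complementary to spectral and
time-domain statistics.

The quadratic-cost sample-entropy pair counting is JIT-compiled with
numba; a full night is analysed in non-overlapping 20-min epochs whose
values are averaged, keeping cost linear in recording length.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "sample_entropy",
    "central_tendency_measure",
    "lempel_ziv_complexity",
    "lz76_phrase_count",
]


@njit(cache=False)
def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Counts (A, B) of length-(m+1) and length-m template matches.

    Chebyshev distance <= r, self-matches excluded, templates taken at
    the first n-m positions (Richman–Moorman convention).
    """
    n = x.shape[0]
    nt = n - m
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def _sampen_exact(x: np.ndarray, m: int, r: float) -> float:
    a, b = _match_counts(np.ascontiguousarray(x, dtype=np.float64), m, r)
    if b == 0 or a == 0:
        # no template matches: the conditional probability is undefined
        return math.nan
    return -math.log(a / b)


def sample_entropy(
    x: np.ndarray,
    m: int = 1,
    r: float | None = None,
    fs: float | None = None,
    epoch_seconds: float | None = None,
) -> float:
    """Sample entropy SampEn(m, r) of a series.

    Parameters
    ----------
    x : array
        Input series (valid samples only).
    m : int
        Template length (default 1).
    r : float, optional
        Match tolerance.  Defaults to ``0.25 * SD(x)`` computed on the
        whole series (also when epoch-averaging).
    fs, epoch_seconds : float, optional
        When both given, the series is cut into non-overlapping epochs
        of ``epoch_seconds`` and the per-epoch entropies are averaged
        (epochs where the statistic is undefined are skipped).  Without
        them the exact whole-series value is returned.

    Returns NaN when no template matches exist anywhere (flagged
    undefined); a constant series returns exactly 0.
    """
    x = np.asarray(x, dtype=float)
    if r is not None and r <= 0:
        raise ValueError("r must be > 0")
    if x.size < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples")
    if r is None:
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            return 0.0  # constant series: all templates match at any r
        r = 0.25 * sd
    if epoch_seconds is None or fs is None:
        return _sampen_exact(x, m, r)
    step = int(round(epoch_seconds * fs))
    if step < m + 2:
        raise ValueError("epoch too short for the template length")
    vals = []
    for start in range(0, x.size - (m + 1), step):
        seg = x[start : start + step]
        if seg.size < m + 2:
            break
        v = _sampen_exact(seg, m, r)
        if not math.isnan(v):
            vals.append(v)
    return float(np.mean(vals)) if vals else math.nan


def central_tendency_measure(x: np.ndarray, rho: float) -> float:
    """Fraction of successive first-difference pairs inside a radius-``rho`` disc.

    Scatter the points ``(d_i, d_{i+1})`` with ``d_i = x_{i+1} - x_i``;
    CTM is the proportion with ``sqrt(d_i^2 + d_{i+1}^2) < rho``.  Low
    variability series concentrate near the origin (CTM → 1).
    """
    x = np.asarray(x, dtype=float)
    if rho <= 0:
        raise ValueError("rho must be > 0")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    d = np.diff(x)
    rad2 = d[:-1] ** 2 + d[1:] ** 2
    return float(np.mean(rad2 < rho * rho))


def lz76_phrase_count(bits: np.ndarray) -> int:
    """Number of phrases c(n) in the exhaustive-history LZ76 parsing.

    Kaspar–Schuster formulation: each new phrase is the shortest suffix
    extension not reproducible by copying from the already-parsed text.
    """
    s = np.ascontiguousarray(bits, dtype=np.uint8)
    n = s.size
    if n == 0:
        raise ValueError("empty sequence")
    if n == 1:
        return 1
    return int(_lz76_kernel(s))


@njit(cache=False)
def _lz76_kernel(s: np.ndarray) -> int:  # pragma: no cover - via lz76_phrase_count
    n = s.shape[0]
    c = 1
    ell = 1
    i = 0
    k = 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[ell + k - 1]:
            k += 1
            if ell + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == ell:
                c += 1
                ell += k_max
                if ell + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def lempel_ziv_complexity(x: np.ndarray) -> float:
    """Normalised Lempel–Ziv complexity of the median-binarised series.

    The series is converted to bits by ``x_i >= median(x)`` and parsed
    with LZ76; the phrase count is normalised as ``c(n) * log2(n) / n``
    so random sequences approach 1 and periodic ones approach 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    bits = (x >= np.median(x)).astype(np.uint8)
    c = lz76_phrase_count(bits)
    n = x.size
    return float(c * np.log2(n) / n)
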