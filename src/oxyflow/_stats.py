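"""Shared low-level statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def four_moments(x: np.ndarray) -> tuple[float, float, float, float, bool]:
    """Mean, unbiased variance, skewness and (non-excess) kurtosis.

    Skewness and kurtosis are the standardised third/fourth central
    moments (biased normalisation, kurtosis of a normal = 3).  A
    zero-variance input yields (mean, 0, 0, 0) with the degenerate flag
    set instead of NaNs.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for moments")
    m1 = float(np.mean(x))
    m2 = float(np.var(x, ddof=1))
    if m2 == 0.0 or not np.isfinite(m2):
        return m1, 0.0, 0.0, 0.0, True
    m3 = float(sps.skew(x, bias=True))
    m4 = float(sps.kurtosis(x, fisher=False, bias=True))
    return m1, m2, m3, m4, False
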