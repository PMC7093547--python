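"""Benchmark fixtures from a published clinical validation study.

A prospective at-home validation of dual-channel OSA screening
(96 held-out patients; 6 No-OSA / 16 mild / 27 moderate / 47 severe)
published its four-class confusion matrices for the three estimator
variants: oximetry only, airflow only and both channels jointly.  Those
matrices, together with the test-set severity prevalences they imply,
are bundled here as fixed inputs so the evaluation layer's published
summary statistics (kappa, accuracies, binary screening metrics,
feasibility thresholds, avoidable-PSG fractions) can be recomputed and
checked end to end without access to the underlying patient data.

Rows are the actual severity grade (No-OSA, mild, moderate, severe in
that order), columns the estimated grade.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CONFUSION_SPO2",
    "CONFUSION_AIRFLOW",
    "CONFUSION_DUAL",
    "BENCHMARK_CONFUSIONS",
    "TEST_CLASS_COUNTS",
    "test_prevalence",
]

CONFUSION_SPO2 = np.array(
    [
        [1, 4, 1, 0],
        [2, 5, 8, 1],
        [0, 2, 24, 1],
        [0, 0, 5, 42],
    ],
    dtype=np.int64,
)

CONFUSION_AIRFLOW = np.array(
    [
        [4, 1, 1, 0],
        [1, 9, 6, 0],
        [1, 6, 14, 6],
        [0, 0, 15, 32],
    ],
    dtype=np.int64,
)

CONFUSION_DUAL = np.array(
    [
        [5, 1, 0, 0],
        [4, 6, 6, 0],
        [0, 3, 23, 1],
        [0, 0, 3, 44],
    ],
    dtype=np.int64,
)

BENCHMARK_CONFUSIONS = {
    "spo2": CONFUSION_SPO2,
    "airflow": CONFUSION_AIRFLOW,
    "dual": CONFUSION_DUAL,
}

#: actual severity class counts in the benchmark test set
TEST_CLASS_COUNTS = (6, 16, 27, 47)


def test_prevalence(cutoff: float) -> float:
    """Pre-test probability of disease at a severity cut-off (5/15/30)."""
    n = sum(TEST_CLASS_COUNTS)
    if cutoff == 5.0:
        positive = sum(TEST_CLASS_COUNTS[1:])
    elif cutoff == 15.0:
        positive = sum(TEST_CLASS_COUNTS[2:])
    elif cutoff == 30.0:
        positive = TEST_CLASS_COUNTS[3]
    else:
        raise ValueError("cutoff must be one of 5, 15, 30 events/h")
    return positive / n
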