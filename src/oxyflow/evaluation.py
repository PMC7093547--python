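"""Agreement and diagnostic-performance statistics for AHI estimators.

The screening question is answered at three levels: how closely the
estimated AHI agrees with the reference as a number (ICC, Bland–Altman
limits of agreement, mountain plot), how well it reproduces the
four-class severity grade (confusion matrix, Cohen's kappa, overall
accuracy) and how it performs as a binary test at the conventional
cut-offs of 5, 15 and 30 events/h (Se/Sp/PPV/NPV, likelihood ratios,
accuracy, ROC AUC).  Confidence intervals come from patient-level
bootstrap resampling.

Two clinical planning tools are included: the minimum positive
likelihood ratio needed to reach a target post-test probability from a
given pre-test probability (the feasibility criterion for portable
monitors), and the fraction of confirmatory polysomnographies avoided
by a triage protocol that trusts the extreme predicted classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .signals import SeverityClass, SEVERITY_THRESHOLDS, severity_of

__all__ = [
    "icc_agreement",
    "bland_altman",
    "mountain_curve",
    "confusion4",
    "kappa",
    "acc4",
    "collapse_at",
    "binary_table",
    "BinaryMetrics",
    "binary_metrics",
    "roc_auc",
    "bootstrap_ci",
    "required_lr_plus",
    "triage_fractions",
    "build_report",
    "DiagnosticReport",
]

CUTOFFS = (5.0, 15.0, 30.0)


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    return a, b


def icc_agreement(a, b) -> float:
    """Two-way, single-measure, absolute-agreement intraclass correlation.

    Computed from the two-way ANOVA mean squares of the n x 2 table
    (subjects x methods); systematic offsets between the methods lower
    the coefficient, unlike Pearson correlation.
    """
    a, b = _paired(a, b)
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    return float((msr - mse) / denom)


def bland_altman(a, b) -> dict[str, float]:
    """Bias and 95% limits of agreement of the differences ``b - a``."""
    a, b = _paired(a, b)
    d = b - a
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "loa_width": 2 * 1.96 * sd,
    }


def mountain_curve(a, b, percentiles=None) -> np.ndarray:
    """Folded empirical percentile curve of the differences ``b - a``.

    Returns an array of (difference, folded percentile) points: the
    p-th percentile maps to p for p <= 50 and to 100 - p above, so a
    well-centred estimator peaks at zero difference.
    """
    a, b = _paired(a, b)
    if percentiles is None:
        percentiles = np.arange(1.0, 100.0)
    d = b - a
    values = np.percentile(d, percentiles)
    folded = np.minimum(percentiles, 100.0 - percentiles)
    return np.column_stack([values, folded])


def confusion4(actual_ahi, estimated_ahi) -> np.ndarray:
    """4x4 severity confusion matrix; rows = actual, columns = estimated."""
    a, b = _paired(actual_ahi, estimated_ahi)
    if a.size == 0:
        raise ValueError("empty input")
    conf = np.zeros((4, 4), dtype=np.int64)
    for x, y in zip(a, b):
        conf[int(severity_of(x)), int(severity_of(y))] += 1
    return conf


def kappa(conf: np.ndarray) -> float:
    """Unweighted Cohen's kappa of a square confusion matrix."""
    conf = np.asarray(conf, dtype=float)
    n = conf.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(conf) / n
    pe = float(np.sum(conf.sum(axis=0) * conf.sum(axis=1))) / n**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def acc4(conf: np.ndarray) -> float:
    """Overall 4-class accuracy, percent."""
    conf = np.asarray(conf, dtype=float)
    n = conf.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    return float(100.0 * np.trace(conf) / n)


def _cutoff_class_index(cutoff: float) -> int:
    try:
        return SEVERITY_THRESHOLDS.index(float(cutoff)) + 1
    except ValueError:
        raise ValueError(
            f"cutoff {cutoff} does not align with the severity boundaries "
            f"{SEVERITY_THRESHOLDS}"
        ) from None


def collapse_at(conf: np.ndarray, cutoff: float) -> dict[str, int]:
    """Merge a 4-class confusion matrix into the 2x2 table at a cut-off.

    Classes at or above the cut-off count as test-positive; the cut-off
    must sit on a severity-class boundary (5, 15 or 30 events/h).
    """
    conf = np.asarray(conf)
    if conf.shape != (4, 4):
        raise ValueError("expected a 4x4 confusion matrix")
    j = _cutoff_class_index(cutoff)
    tp = int(conf[j:, j:].sum())
    fn = int(conf[j:, :j].sum())
    fp = int(conf[:j, j:].sum())
    tn = int(conf[:j, :j].sum())
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def binary_table(actual_ahi, estimated_ahi, cutoff: float) -> dict[str, int]:
    """2x2 table straight from paired AHI vectors at an arbitrary cut-off."""
    a, b = _paired(actual_ahi, estimated_ahi)
    pos_a = a >= cutoff
    pos_b = b >= cutoff
    return {
        "tp": int(np.sum(pos_a & pos_b)),
        "fp": int(np.sum(~pos_a & pos_b)),
        "fn": int(np.sum(pos_a & ~pos_b)),
        "tn": int(np.sum(~pos_a & ~pos_b)),
    }


@dataclass
class BinaryMetrics:
    """Standard 2x2 screening metrics; undefined branches hold NaN."""

    Se: float
    Sp: float
    PPV: float
    NPV: float
    LR_plus: float
    LR_minus: float
    Acc: float
    AUC: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("Se", "Sp", "PPV", "NPV", "LR_plus", "LR_minus", "Acc", "AUC")}


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def binary_metrics(t: dict[str, int]) -> BinaryMetrics:
    """Se/Sp/PPV/NPV (percent), likelihood ratios and accuracy of a 2x2 table."""
    tp, fp, fn, tn = t["tp"], t["fp"], t["fn"], t["tn"]
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty 2x2 table")
    se = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    lr_plus = (se / 100.0) / (1.0 - sp / 100.0) if sp < 100.0 else math.nan
    lr_minus = (1.0 - se / 100.0) / (sp / 100.0) if sp > 0.0 else math.nan
    return BinaryMetrics(
        Se=se,
        Sp=sp,
        PPV=_ratio(tp, tp + fp),
        NPV=_ratio(tn, tn + fn),
        LR_plus=lr_plus,
        LR_minus=lr_minus,
        Acc=_ratio(tp + tn, n),
    )


def roc_auc(scores, labels) -> float:
    """Trapezoidal AUC sweeping the continuous estimated AHI as threshold.

    Equals the Mann–Whitney probability that a positive case scores
    above a negative one (ties counted half).
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need both classes to compute an AUC")
    return float(roc_auc_score(labels.astype(int), np.asarray(scores, dtype=float)))


def bootstrap_ci(
    metric, a, b, B: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric(a[idx], b[idx])`` over patients."""
    if B < 100:
        raise ValueError("B must be >= 100 for a stable percentile CI")
    a, b = _paired(a, b)
    rng = np.random.default_rng(seed)
    n = a.size
    vals = np.empty(B)
    undefined = 0
    for i in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            v = float(metric(a[idx], b[idx]))
        except (ValueError, ZeroDivisionError):
            v = math.nan
        if math.isnan(v):
            undefined += 1
        vals[i] = v
    if undefined > 0.10 * B:
        warnings.warn(
            f"metric undefined on {undefined}/{B} resamples; CI may be too wide",
            stacklevel=2,
        )
    good = vals[~np.isnan(vals)]
    if good.size == 0:
        return math.nan, math.nan
    alpha = (1.0 - level) / 2.0
    return (
        float(np.percentile(good, 100 * alpha)),
        float(np.percentile(good, 100 * (1 - alpha))),
    )


def required_lr_plus(pretest: float, posttest: float = 0.95) -> float:
    """Minimum LR+ turning a pre-test probability into a post-test one."""
    if not 0 < pretest < 1 or not 0 < posttest < 1:
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    pre_odds = pretest / (1.0 - pretest)
    post_odds = posttest / (1.0 - posttest)
    return post_odds / pre_odds


def triage_fractions(conf: np.ndarray, protocol: str = "conservative") -> float:
    """Percent of confirmatory PSGs avoided by trusting extreme predictions.

    ``conservative``: patients predicted No-OSA (follow-up) or severe
    (straight to treatment) skip PSG.  ``extended`` additionally trusts
    the predicted-moderate column.
    """
    conf = np.asarray(conf)
    if conf.shape != (4, 4):
        raise ValueError("expected a 4x4 confusion matrix")
    n = conf.sum()
    cols = conf.sum(axis=0)
    if protocol == "conservative":
        avoided = cols[int(SeverityClass.NO_OSA)] + cols[int(SeverityClass.SEVERE)]
    elif protocol == "extended":
        avoided = (
            cols[int(SeverityClass.NO_OSA)]
            + cols[int(SeverityClass.MODERATE)]
            + cols[int(SeverityClass.SEVERE)]
        )
    else:
        raise ValueError(f"unknown protocol: {protocol}")
    return float(100.0 * avoided / n)


@dataclass
class DiagnosticReport:
    """All agreement/diagnostic statistics per model, JSON-serialisable."""

    models: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"models": self.models}


def _model_block(actual, estimated, B: int, seed: int) -> dict:
    conf = confusion4(actual, estimated)
    block = {
        "icc": icc_agreement(actual, estimated),
        "icc_ci": bootstrap_ci(icc_agreement, actual, estimated, B=B, seed=seed),
        "bland_altman": bland_altman(actual, estimated),
        "mountain": mountain_curve(actual, estimated).tolist(),
        "confusion4": conf.tolist(),
        "kappa": kappa(conf),
        "kappa_ci": bootstrap_ci(
            lambda x, y: kappa(confusion4(x, y)), actual, estimated, B=B, seed=seed
        ),
        "acc4": acc4(conf),
        "acc4_ci": bootstrap_ci(
            lambda x, y: acc4(confusion4(x, y)), actual, estimated, B=B, seed=seed
        ),
        "avoidable_psg": {
            "conservative": triage_fractions(conf, "conservative"),
            "extended": triage_fractions(conf, "extended"),
        },
        "cutoffs": {},
    }
    for cutoff in CUTOFFS:
        table = binary_table(actual, estimated, cutoff)
        metrics = binary_metrics(table)
        labels = np.asarray(actual) >= cutoff
        if labels.any() and not labels.all():
            metrics.AUC = roc_auc(estimated, labels)
        entry = metrics.to_dict()
        entry["table"] = table
        entry["Acc_ci"] = bootstrap_ci(
            lambda x, y, c=cutoff: binary_metrics(binary_table(x, y, c)).Acc,
            actual,
            estimated,
            B=B,
            seed=seed,
        )
        block["cutoffs"][f"{cutoff:g}"] = entry
    return block


def build_report(
    actual, estimated_per_model: dict[str, np.ndarray], B: int = 1000, seed: int = 0
) -> DiagnosticReport:
    """Aggregate every statistic for each model against the shared reference."""
    actual = np.asarray(actual, dtype=float)
    report = DiagnosticReport()
    for name, estimated in estimated_per_model.items():
        estimated = np.asarray(estimated, dtype=float)
        if estimated.shape != actual.shape:
            raise ValueError(f"model {name}: estimate/reference length mismatch")
        report.models[name] = _model_block(actual, estimated, B=B, seed=seed)
    return report
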