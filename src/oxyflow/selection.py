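"""Bootstrap-stabilised fast correlation-based filter (FCBF).

Feature relevance and redundancy are both measured by symmetrical
uncertainty ``SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y))`` on discretised
variables.  FCBF ranks features by SU with the target and keeps a
feature only if no stronger, already-kept feature is *predominant* over
it (more informative about the feature than the feature is about the
target).

To decouple the selection from any particular training sample, FCBF is
repeated on B bootstrap replicates of the training rows; a feature's
significance is the number of replicates in which it was selected, and
the final subset keeps the features whose significance exceeds the mean
significance of the whole input set.

Continuous features are discretised per replicate by Fayyad–Irani
recursive entropy minimisation with the MDL stopping criterion, against
the four-class OSA severity grade of the reference AHI.  Features that
admit no MDL-accepted cut point collapse to a single bin and carry zero
symmetrical uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureTable
from .signals import severity_of

__all__ = [
    "symmetrical_uncertainty",
    "mdl_discretise",
    "fcbf",
    "bootstrap_fcbf",
    "SelectionResult",
]


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(X, Y) in [0, 1] from the plug-in joint distribution.

    1 when the (non-constant) variables determine each other, 0 when the
    empirical joint factorises.  Defined as 0 when both variables are
    constant (zero total entropy).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    hx = _entropy_bits(joint.sum(axis=1))
    hy = _entropy_bits(joint.sum(axis=0))
    hxy = _entropy_bits(joint.ravel())
    denom = hx + hy
    if denom == 0.0:
        return 0.0
    mi = hx + hy - hxy
    return float(np.clip(2.0 * mi / denom, 0.0, 1.0))


def _class_cumcounts(y: np.ndarray, k: int) -> np.ndarray:
    onehot = np.zeros((y.size, k))
    onehot[np.arange(y.size), y] = 1.0
    return np.cumsum(onehot, axis=0)


def _best_mdl_cut(x: np.ndarray, y: np.ndarray, k: int) -> tuple[float, int] | None:
    """Best entropy-minimising cut of a sorted segment, or None if MDL rejects."""
    n = x.size
    if n < 4:
        return None
    cand = np.flatnonzero(x[1:] > x[:-1]) + 1  # split before index i
    if cand.size == 0:
        return None
    cum = _class_cumcounts(y, k)
    total = cum[-1]
    ent_s = _entropy_bits(total)
    left = cum[cand - 1]
    right = total - left
    nl = left.sum(axis=1)
    nr = right.sum(axis=1)

    def _ent_rows(counts, ns):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / ns[:, None]
            logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return -np.sum(p * logp, axis=1)

    ent_l = _ent_rows(left, nl)
    ent_r = _ent_rows(right, nr)
    weighted = (nl * ent_l + nr * ent_r) / n
    best = int(np.argmin(weighted))
    gain = ent_s - weighted[best]
    k1 = int(np.count_nonzero(left[best]))
    k2 = int(np.count_nonzero(right[best]))
    delta = np.log2(3.0**k - 2.0) - (k * ent_s - k1 * ent_l[best] - k2 * ent_r[best])
    if gain <= (np.log2(n - 1) + delta) / n:
        return None
    pos = int(cand[best])
    cut = 0.5 * (x[pos - 1] + x[pos])
    return cut, pos


def mdl_discretise(x: np.ndarray, y_classes: np.ndarray) -> np.ndarray:
    """Fayyad–Irani MDL supervised binning; returns integer bin codes.

    Features yielding no accepted cut point collapse to a single bin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_classes)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    classes, yc = np.unique(ys, return_inverse=True)
    k = classes.size
    cuts: list[float] = []

    def _recurse(lo: int, hi: int) -> None:
        res = _best_mdl_cut(xs[lo:hi], yc[lo:hi], k)
        if res is None:
            return
        cut, pos = res
        cuts.append(cut)
        _recurse(lo, lo + pos)
        _recurse(lo + pos, hi)

    if k > 1:
        _recurse(0, x.size)
    return np.searchsorted(np.sort(cuts), x, side="right").astype(np.int64)


def fcbf(
    features: pd.DataFrame, target: np.ndarray, delta: float = 0.0
) -> list[str]:
    """FCBF on already-discretised features; returns selected names in rank order.

    Features with relevance ``SU(f, target) <= delta`` are dropped; the
    rest are ranked by descending relevance (ties broken by feature
    name) and pruned: a feature is removed when an already-kept,
    more relevant feature is predominant over it.
    """
    if features.shape[1] == 0:
        raise ValueError("no features to select from")
    target = np.asarray(target)
    names = list(features.columns)
    su_target = {
        name: symmetrical_uncertainty(features[name].to_numpy(), target)
        for name in names
    }
    ranked = sorted(
        (name for name in names if su_target[name] > delta),
        key=lambda name: (-su_target[name], name),
    )
    selected: list[str] = []
    for name in ranked:
        fj = features[name].to_numpy()
        predominant = any(
            symmetrical_uncertainty(features[kept].to_numpy(), fj) >= su_target[name]
            for kept in selected
        )
        if not predominant:
            selected.append(name)
    return selected


@dataclass
class SelectionResult:
    """Outcome of the bootstrap-FCBF procedure."""

    counts: dict[str, int]
    threshold: float
    selected: list[str]
    B: int
    seed: int
    redrawn_replicates: int = 0

    def __post_init__(self) -> None:
        if abs(self.threshold - float(np.mean(list(self.counts.values())))) > 1e-9:
            raise ValueError("threshold must equal the mean selection count")

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "threshold": self.threshold,
            "selected": self.selected,
            "B": self.B,
            "seed": self.seed,
            "redrawn_replicates": self.redrawn_replicates,
        }


def bootstrap_fcbf(
    table: FeatureTable, B: int = 1000, seed: int = 0, delta: float = 0.0
) -> SelectionResult:
    """Run FCBF on B bootstrap replicates of the training rows.

    Per replicate the rows are resampled with replacement, the target
    AHI is graded into the four severity classes, each feature is
    MDL-discretised against those classes and FCBF is run; the per-
    feature selection counts, their mean (the significance threshold)
    and the features above it make up the result.  Deterministic under
    ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = table.y.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("bootstrap_fcbf requires a reference AHI for every row")
    X = table.X.to_numpy(dtype=float)
    names = table.feature_names
    classes = np.array([int(severity_of(v)) for v in y])
    n = y.size
    rng = np.random.default_rng(seed)
    counts = dict.fromkeys(names, 0)
    redrawn = 0
    done = 0
    while done < B:
        idx = rng.integers(0, n, size=n)
        boot_classes = classes[idx]
        if np.unique(boot_classes).size < 2:
            redrawn += 1  # degenerate single-class resample: redraw
            continue
        disc = {
            name: mdl_discretise(X[idx, j], boot_classes)
            for j, name in enumerate(names)
        }
        picked = fcbf(pd.DataFrame(disc), boot_classes, delta=delta)
        for name in picked:
            counts[name] += 1
        done += 1
    threshold = float(np.mean(list(counts.values())))
    selected = sorted(
        (name for name in names if counts[name] > threshold),
        key=lambda name: (-counts[name], name),
    )
    return SelectionResult(
        counts=counts,
        threshold=threshold,
        selected=selected,
        B=B,
        seed=seed,
        redrawn_replicates=redrawn,
    )
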