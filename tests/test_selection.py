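import math

import numpy as np
import pandas as pd
import pytest

from oxyflow.features import TARGET_COLUMN, FeatureTable
from oxyflow.selection import (
    bootstrap_fcbf,
    fcbf,
    mdl_discretise,
    symmetrical_uncertainty,
)


def entropy_oracle(values):
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return -np.sum(p * np.log2(p))


def joint_entropy_oracle(x, y):
    pairs = list(zip(x.tolist(), y.tolist()))
    _, counts = np.unique(np.array([hash(p) for p in pairs]), return_counts=True)
    p = counts / counts.sum()
    return -np.sum(p * np.log2(p))


def su_oracle(x, y):
    hx = entropy_oracle(x)
    hy = entropy_oracle(y)
    if hx + hy == 0:
        return 0.0
    mi = hx + hy - joint_entropy_oracle(x, y)
    return 2.0 * mi / (hx + hy)


def fcbf_oracle(frame, target, delta=0.0):
    """Literal FCBF: rank by SU with target, prune by predominance."""
    su_t = {c: su_oracle(frame[c].to_numpy(), target) for c in frame.columns}
    ranked = sorted((c for c in frame.columns if su_t[c] > delta), key=lambda c: (-su_t[c], c))
    kept = []
    for c in ranked:
        if not any(
            su_oracle(frame[k].to_numpy(), frame[c].to_numpy()) >= su_t[c] for k in kept
        ):
            kept.append(c)
    return kept


class TestSymmetricalUncertainty:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 200)
        x = rng.integers(0, rng.integers(2, 6), n)
        y = rng.integers(0, rng.integers(2, 6), n)
        assert symmetrical_uncertainty(x, y) == pytest.approx(su_oracle(x, y), abs=1e-12)

    def test_identical_variables_give_one(self):
        x = np.array([0, 1, 2, 0, 1, 2, 0, 1])
        assert symmetrical_uncertainty(x, x) == pytest.approx(1.0)

    def test_independent_large_sample_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 20000)
        y = rng.integers(0, 2, 20000)
        assert symmetrical_uncertainty(x, y) < 0.01

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 100)
        y = rng.integers(0, 4, 100)
        assert symmetrical_uncertainty(x, y) == pytest.approx(symmetrical_uncertainty(y, x))

    def test_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x = rng.integers(0, 5, 50)
            y = rng.integers(0, 5, 50)
            assert 0.0 <= symmetrical_uncertainty(x, y) <= 1.0

    def test_constant_inputs_give_zero(self):
        assert symmetrical_uncertainty(np.zeros(10, int), np.zeros(10, int)) == 0.0


class TestMDLDiscretise:
    def test_separable_feature_gets_cut(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 100)
        x = np.concatenate([rng.normal(0, 0.3, 100), rng.normal(5, 0.3, 100)])
        codes = mdl_discretise(x, y)
        assert np.unique(codes).size >= 2
        # the induced partition should separate the classes almost perfectly
        assert abs(np.corrcoef(codes, y)[0, 1]) > 0.95

    def test_uninformative_feature_single_bin(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        x = rng.normal(size=200)
        codes = mdl_discretise(x, y)
        assert np.unique(codes).size == 1

    def test_codes_monotone_in_value(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1, 2], 60)
        x = np.concatenate([rng.normal(c * 4, 0.3, 60) for c in range(3)])
        codes = mdl_discretise(x, y)
        order = np.argsort(x)
        assert np.all(np.diff(codes[order]) >= 0)


class TestFCBF:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        n_feat = rng.integers(2, 6)
        target = rng.integers(0, 3, n)
        frame = pd.DataFrame(
            {
                f"f{j}": np.where(
                    rng.random(n) < 0.6, target, rng.integers(0, 3, n)
                ) if j % 2 == 0 else rng.integers(0, 4, n)
                for j in range(n_feat)
            }
        )
        assert fcbf(frame, target) == fcbf_oracle(frame, target)

    def test_redundant_copy_pruned(self):
        rng = np.random.default_rng(9)
        target = rng.integers(0, 2, 100)
        noisy = np.where(rng.random(100) < 0.8, target, 1 - target)
        frame = pd.DataFrame({"a": noisy, "a_copy": noisy, "noise": rng.integers(0, 2, 100)})
        kept = fcbf(frame, target)
        assert sum(c in kept for c in ("a", "a_copy")) == 1

    def test_irrelevant_features_dropped(self):
        rng = np.random.default_rng(10)
        target = rng.integers(0, 2, 500)
        frame = pd.DataFrame({"signal": target, "junk": rng.integers(0, 2, 500)})
        kept = fcbf(frame, target)
        assert kept[0] == "signal"
        assert "junk" not in kept or su_oracle(frame["junk"].to_numpy(), target) > 0

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            fcbf(pd.DataFrame(index=range(5)), np.zeros(5, int))


class TestBootstrapFCBF:
    @staticmethod
    def _table(n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0, 60, n)
        df = pd.DataFrame(
            {
                "good": y + rng.normal(0, 3, n),
                "weak": y + rng.normal(0, 40, n),
                "junk": rng.normal(size=n),
            }
        )
        df[TARGET_COLUMN] = y
        return FeatureTable(df)

    def test_deterministic(self):
        t = self._table()
        a = bootstrap_fcbf(t, B=50, seed=4)
        b = bootstrap_fcbf(t, B=50, seed=4)
        assert a.counts == b.counts and a.selected == b.selected

    def test_threshold_is_mean_count(self):
        r = bootstrap_fcbf(self._table(), B=50, seed=5)
        assert r.threshold == pytest.approx(np.mean(list(r.counts.values())))
        assert r.selected == [k for k, v in r.counts.items() if v > r.threshold]

    def test_informative_feature_selected(self):
        r = bootstrap_fcbf(self._table(), B=100, seed=6)
        assert "good" in r.selected
        assert "junk" not in r.selected
        assert r.counts["good"] > r.counts["junk"]

    def test_counts_bounded_by_B(self):
        r = bootstrap_fcbf(self._table(), B=50, seed=7)
        assert all(0 <= v <= 50 for v in r.counts.values())
        assert r.B == 50

    def test_serialisable(self):
        r = bootstrap_fcbf(self._table(), B=50, seed=8)
        d = r.to_dict()
        assert set(d) == {"counts", "threshold", "selected", "B", "seed", "redrawn_replicates"}

    def test_invalid_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_fcbf(self._table(), B=0)
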