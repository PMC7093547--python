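import math

import numpy as np
import pandas as pd
import pytest

from oxyflow.evaluation import (
    acc4,
    binary_metrics,
    binary_table,
    bland_altman,
    bootstrap_ci,
    build_report,
    collapse_at,
    confusion4,
    icc_agreement,
    kappa,
    mountain_curve,
    required_lr_plus,
    roc_auc,
    triage_fractions,
)
from oxyflow.reference import CONFUSION_DUAL


def labels_from_confusion(conf):
    actual, est = [], []
    for i in range(4):
        for j in range(4):
            actual += [i] * conf[i][j]
            est += [j] * conf[i][j]
    return np.array(actual), np.array(est)


class TestICC:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pingouin_oracle(self, seed):
        import pingouin as pg

        rng = np.random.default_rng(seed)
        n = rng.integers(10, 60)
        a = rng.uniform(0, 60, n)
        b = a + rng.normal(rng.uniform(-5, 5), rng.uniform(1, 10), n)
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(n), 2),
                "rater": np.repeat(["A", "B"], n),
                "score": np.concatenate([a, b]),
            }
        )
        icc = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        # two-way random, single measure, absolute agreement
        want = float(icc.loc[icc["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_agreement(a, b) == pytest.approx(want, abs=1e-10)

    def test_perfect_agreement_is_one(self):
        a = np.arange(10.0)
        assert icc_agreement(a, a) == pytest.approx(1.0)

    def test_systematic_offset_lowers_icc_below_pearson(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 60, 50)
        b = a + 20.0
        assert icc_agreement(a, b) < 0.9
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_agreement([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_known_differences(self):
        # differences {-2, 0, 2}: bias 0, SD 2, LoA width 2*1.96*2 = 7.84
        a = np.array([10.0, 20.0, 30.0])
        b = a + np.array([-2.0, 0.0, 2.0])
        ba = bland_altman(a, b)
        assert ba["bias"] == pytest.approx(0.0)
        assert ba["loa_width"] == pytest.approx(7.84)
        assert ba["loa_low"] == pytest.approx(-3.92)
        assert ba["loa_high"] == pytest.approx(3.92)

    def test_bias_sign_convention(self):
        a = np.zeros(10)
        b = np.full(10, 3.0)
        assert bland_altman(a, b)["bias"] == pytest.approx(3.0)


class TestMountain:
    def test_folds_at_median(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=500)
        curve = mountain_curve(a, a + rng.normal(size=500))
        values, folded = curve[:, 0], curve[:, 1]
        assert folded.max() <= 50.0
        assert folded[0] == 1.0 and folded[-1] == 1.0
        # the peak sits at the median difference
        assert values[np.argmax(folded)] == pytest.approx(np.median(curve[:, 0]), abs=0.2)
        assert np.all(np.diff(values) >= 0)

    def test_identical_vectors_zero_differences(self):
        a = np.arange(20.0)
        curve = mountain_curve(a, a)
        assert np.all(curve[:, 0] == 0.0)


class TestConfusionAndKappa:
    def test_confusion4_from_paired_ahis(self):
        actual = np.array([2.0, 10.0, 20.0, 40.0, 3.0])
        est = np.array([1.0, 20.0, 20.0, 29.0, 6.0])
        conf = confusion4(actual, est)
        assert conf[0, 0] == 1 and conf[0, 1] == 1
        assert conf[1, 2] == 1 and conf[2, 2] == 1 and conf[3, 2] == 1
        assert conf.sum() == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_kappa_matches_sklearn(self, seed):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        actual = rng.integers(0, 4, 200)
        est = np.where(rng.random(200) < 0.6, actual, rng.integers(0, 4, 200))
        conf = np.zeros((4, 4), dtype=int)
        for i, j in zip(actual, est):
            conf[i, j] += 1
        assert kappa(conf) == pytest.approx(cohen_kappa_score(actual, est), abs=1e-12)

    def test_kappa_one_iff_diagonal(self):
        assert kappa(np.diag([5, 5, 5, 5])) == pytest.approx(1.0)
        off = np.diag([5, 5, 5, 5])
        off[0, 1] = 1
        assert kappa(off) < 1.0

    def test_acc4_is_diagonal_fraction(self):
        conf = np.array(CONFUSION_DUAL)
        assert acc4(conf) == pytest.approx(100.0 * np.trace(conf) / conf.sum())

    def test_acc4_invariant_under_permutation(self):
        conf = np.array(CONFUSION_DUAL)
        perm = [2, 0, 3, 1]
        assert acc4(conf[np.ix_(perm, perm)]) == pytest.approx(acc4(conf))


class TestBinary:
    def test_collapse_consistent_with_paired_vectors(self):
        actual, est = labels_from_confusion(np.array(CONFUSION_DUAL))
        # map class indices back to representative AHIs
        reps = np.array([2.0, 10.0, 20.0, 40.0])
        conf = confusion4(reps[actual], reps[est])
        for cutoff in (5.0, 15.0, 30.0):
            assert collapse_at(conf, cutoff) == binary_table(reps[actual], reps[est], cutoff)

    def test_metrics_from_known_table(self):
        m = binary_metrics({"tp": 44, "fp": 1, "fn": 3, "tn": 48})
        assert m.Se == pytest.approx(100 * 44 / 47)
        assert m.Sp == pytest.approx(100 * 48 / 49)
        assert m.PPV == pytest.approx(100 * 44 / 45)
        assert m.NPV == pytest.approx(100 * 48 / 51)
        assert m.Acc == pytest.approx(100 * 92 / 96)
        assert m.LR_plus == pytest.approx((44 / 47) / (1 / 49))

    def test_perfect_specificity_gives_nan_lr(self):
        m = binary_metrics({"tp": 10, "fp": 0, "fn": 0, "tn": 10})
        assert math.isnan(m.LR_plus)
        assert m.LR_minus == pytest.approx(0.0)

    def test_identity_lr_times_preodds_is_postodds(self):
        m = binary_metrics({"tp": 30, "fp": 5, "fn": 10, "tn": 55})
        pre_odds = 40 / 60
        post_odds = (m.PPV / 100) / (1 - m.PPV / 100)
        assert m.LR_plus * pre_odds == pytest.approx(post_odds)

    def test_arbitrary_cutoff_allowed_on_vectors(self):
        actual = np.array([1.0, 8.0, 12.0, 25.0])
        est = np.array([2.0, 9.0, 9.0, 30.0])
        t = binary_table(actual, est, 10.0)
        assert t == {"tp": 1, "fp": 0, "fn": 1, "tn": 2}


class TestAUC:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_u_statistic(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(0, 60, 100)
        labels = rng.random(100) < 0.5
        pos = scores[labels]
        neg = scores[~labels]
        u = np.mean([
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        ])
        assert roc_auc(scores, labels) == pytest.approx(u, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


class TestBootstrapCI:
    def test_deterministic_and_ordered(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 60, 40)
        b = a + rng.normal(0, 5, 40)
        ci1 = bootstrap_ci(icc_agreement, a, b, B=200, seed=1)
        ci2 = bootstrap_ci(icc_agreement, a, b, B=200, seed=1)
        assert ci1 == ci2
        assert ci1[0] <= ci1[1]

    def test_contains_point_estimate_typically(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(0, 60, 60)
        b = a + rng.normal(0, 5, 60)
        lo, hi = bootstrap_ci(icc_agreement, a, b, B=300, seed=2)
        assert lo <= icc_agreement(a, b) <= hi

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(icc_agreement, np.arange(10.0), np.arange(10.0), B=10)


class TestFeasibility:
    def test_required_lr_formula(self):
        # post-odds / pre-odds with post-test probability 0.95
        assert required_lr_plus(0.5) == pytest.approx(19.0)
        assert required_lr_plus(0.95) == pytest.approx(1.0)

    def test_boundaries_rejected(self):
        for p in (0.0, 1.0):
            with pytest.raises(ValueError):
                required_lr_plus(p)

    def test_triage_identity_matrix(self):
        conf = np.diag([10, 20, 30, 40])
        assert triage_fractions(conf, "conservative") == pytest.approx(100 * 50 / 100)
        assert triage_fractions(conf, "extended") == pytest.approx(100 * 80 / 100)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            triage_fractions(np.eye(4, dtype=int), "bogus")


class TestReport:
    def test_identical_vectors_perfect_scores(self):
        rng = np.random.default_rng(11)
        actual = np.concatenate([rng.uniform(lo, hi, 4) for lo, hi in
                                 ((0, 5), (5, 15), (15, 30), (30, 60))])
        rep = build_report(actual, {"m": actual.copy()}, B=100, seed=0)
        block = rep.models["m"]
        assert block["icc"] == pytest.approx(1.0)
        assert block["kappa"] == pytest.approx(1.0)
        assert block["acc4"] == pytest.approx(100.0)

    def test_report_internally_consistent(self):
        rng = np.random.default_rng(12)
        actual = rng.uniform(0, 60, 50)
        est = np.maximum(actual + rng.normal(0, 8, 50), 0)
        rep = build_report(actual, {"m": est}, B=100, seed=0)
        block = rep.models["m"]
        lo, hi = block["icc_ci"]
        assert lo <= block["icc"] <= hi
        conf = np.array(block["confusion4"])
        assert conf.sum() == 50
        for cutoff in ("5", "15", "30"):
            sub = block["cutoffs"][cutoff]
            t = sub["table"]
            assert t["tp"] + t["fp"] + t["fn"] + t["tn"] == 50
            assert sub["Acc"] == pytest.approx(100 * (t["tp"] + t["tn"]) / 50)
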