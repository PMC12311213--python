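"""Diagnostic metrics, bootstrap CIs, ROC/AUC, DeLong, DCA, agreement, RM-ANOVA."""

import numpy as np
import pytest

from lymphgraph.evaluation import (
    ConfusionCounts,
    agreement_matrix,
    bootstrap_ci,
    confusion_at_cutoff,
    decision_curve,
    delong_test,
    delong_variance,
    diagnostic_metrics,
    diagnostic_report,
    oneway_anova,
    rm_anova,
    roc_auc,
)


def exhaustive_auc(prob, y):
    """Exact pairwise-counting oracle: P(pos > neg) + 0.5 P(=)."""
    pos = prob[y == 1]
    neg = prob[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_cutoff_zero_all_positive(self):
        c = confusion_at_cutoff([0.2, 0.9], [0, 1], 0.0)
        assert c.TN == 0 and c.FN == 0 and c.TP == 1 and c.FP == 1

    def test_cutoff_above_one_all_negative(self):
        c = confusion_at_cutoff([0.2, 0.9], [0, 1], 1.0 + 1e-9)
        assert c.TP == 0 and c.FP == 0 and c.TN == 1 and c.FN == 1

    def test_enumerated_example(self):
        c = confusion_at_cutoff([0.9, 0.2, 0.6, 0.4], [1, 0, 1, 0], 0.5)
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_cutoff([0.5], [0, 1], 0.5)


class TestDiagnosticMetrics:
    def test_hand_computed_values(self):
        m = diagnostic_metrics(ConfusionCounts(TP=3, FP=1, TN=4, FN=2))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["npv"] == pytest.approx(2 / 3)

    def test_perfect_classifier(self):
        m = diagnostic_metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert all(v == 1.0 for v in m.values())

    def test_empty_denominator_gives_nan(self):
        m = diagnostic_metrics(ConfusionCounts(TP=0, FP=2, TN=3, FN=0))
        assert np.isnan(m["sensitivity"])

    def test_printed_npv_audit_mode_is_complement(self):
        c = ConfusionCounts(TP=3, FP=1, TN=4, FN=2)
        std = diagnostic_metrics(c)["npv"]
        printed = diagnostic_metrics(c, printed_npv=True)["npv"]
        assert std + printed == pytest.approx(1.0)


class TestRocAuc:
    def test_derived_example(self):
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_perfectly_ordered_gives_one(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_pair_counting(self, rng):
        # exact agreement with the O(n^2) oracle on many random instances
        for _ in range(50):
            n = rng.integers(10, 200)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            prob = np.round(rng.random(n), 2)  # coarse grid forces ties
            _, auc = roc_auc(prob, y)
            assert auc == pytest.approx(exhaustive_auc(prob, y), abs=1e-12)


class TestBootstrapCI:
    def test_constant_correct_predictions_collapse(self):
        y = np.array([0, 1] * 20)
        prob = y.astype(float)
        lo, hi = bootstrap_ci(prob, y, "accuracy", n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_seeded_reproducibility(self, rng):
        y = rng.integers(0, 2, 60)
        prob = rng.random(60)
        a = bootstrap_ci(prob, y, "auc", n_boot=300, seed=5)
        b = bootstrap_ci(prob, y, "auc", n_boot=300, seed=5)
        assert a == b

    def test_estimate_inside_interval(self, rng):
        y = rng.integers(0, 2, 100)
        prob = np.clip(rng.normal(0.5, 0.2, 100) + 0.2 * y, 0, 1)
        rep = diagnostic_report(prob, y, n_boot=300, seed=1)
        for name, est in rep.estimates.items():
            lo, hi = rep.intervals[name]
            assert lo <= est <= hi

    def test_n_boot_floor(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci(rng.random(10), rng.integers(0, 2, 10), "auc", n_boot=50)


class TestDeLong:
    def test_identical_models_p_one(self, rng):
        y = rng.integers(0, 2, 40)
        y[:3] = [0, 1, 1]
        prob = rng.random(40)
        auc_a, auc_b, z, p = delong_test(prob, prob, y)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_swap_antisymmetry(self, rng):
        y = np.array([0, 1] * 25)
        pa, pb = rng.random(50), rng.random(50)
        _, _, z1, p1 = delong_test(pa, pb, y)
        _, _, z2, p2 = delong_test(pb, pa, y)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_auc_matches_roc_auc(self, rng):
        y = np.array([0, 1] * 30)
        pa, pb = rng.random(60), rng.random(60)
        auc_a, auc_b, _, _ = delong_test(pa, pb, y)
        assert auc_a == pytest.approx(roc_auc(pa, y)[1])
        assert auc_b == pytest.approx(roc_auc(pb, y)[1])

    def test_variance_against_bootstrap_oracle(self):
        # n=30 paired design; 20k stratified case resamples as the oracle
        rng = np.random.default_rng(7)
        y = np.array([1] * 12 + [0] * 18)
        prob = np.clip(rng.normal(0.6, 0.2, 30) + 0.15 * y, 0, 1)
        v = delong_variance(prob, y)
        pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        aucs = np.empty(20000)
        for b in range(20000):
            idx = np.concatenate([rng.choice(pos, pos.size), rng.choice(neg, neg.size)])
            aucs[b] = roc_auc(prob[idx], y[idx])[1]
        assert v == pytest.approx(np.var(aucs, ddof=1), rel=0.10)

    def test_obvious_difference_is_significant(self, rng):
        y = np.array([0, 1] * 50)
        good = 0.8 * y + 0.2 * rng.random(100)
        junk = rng.random(100)
        *_, p = delong_test(good, junk, y)
        assert p < 0.01


class TestDecisionCurve:
    def test_treat_none_is_zero(self, rng):
        y = rng.integers(0, 2, 50)
        df = decision_curve(rng.random(50), y)
        assert np.all(df["net_benefit_none"] == 0.0)

    def test_formula_arithmetic(self):
        # n=10, TP=4, FP=2 at p_t = 0.2: NB = 0.4 - 0.2 * 0.25 = 0.35
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 1, 0])
        prob = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.5, 0.1, 0.1, 0.05, 0.05])
        df = decision_curve(prob, y, pt_grid=np.array([0.2]))
        assert df["net_benefit_model"].iloc[0] == pytest.approx(0.35)

    def test_treat_all_reference(self):
        y = np.array([1, 1, 0, 0, 0] * 2)  # prevalence 0.4
        df = decision_curve(np.linspace(0, 1, 10), y, pt_grid=np.array([0.2]))
        assert df["net_benefit_all"].iloc[0] == pytest.approx(0.4 - 0.6 * 0.25)

    def test_net_benefit_never_exceeds_prevalence(self, rng):
        y = rng.integers(0, 2, 80)
        prob = rng.random(80)
        df = decision_curve(prob, y)
        assert np.all(df["net_benefit_model"] <= y.mean() + 1e-12)

    def test_invalid_grid_rejected(self, rng):
        y = rng.integers(0, 2, 20)
        with pytest.raises(ValueError):
            decision_curve(rng.random(20), y, pt_grid=np.array([0.0, 0.5]))


class TestAgreementAndAnova:
    def test_model_versus_itself_r_one(self, rng):
        p = rng.random(30)
        r = agreement_matrix({"a": p, "b": rng.random(30)})
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(r.loc["b", "a"])

    def test_constant_model_gives_nan(self, rng):
        r = agreement_matrix({"a": np.full(10, 0.5), "b": rng.random(10)})
        assert np.isnan(r.loc["a", "b"])

    def test_rm_anova_degrees_of_freedom_structure(self, rng):
        # k = 4 models on n = 112 paired cases: df = (3, 333)
        models = {f"m{i}": rng.random(112) for i in range(4)}
        f, dfn, dfd, p = rm_anova(models)
        assert dfn == 3.0
        assert dfd == 333.0

    def test_identical_models_f_zero(self, rng):
        p = rng.random(20)
        f, dfn, dfd, pv = rm_anova({"a": p.copy(), "b": p.copy(), "c": p.copy()})
        assert f == 0.0 and pv == 1.0

    def test_shifted_model_detected(self, rng):
        base = rng.random(60)
        f, _, _, p = rm_anova({"a": base, "b": base + 0.2, "c": base - 0.1})
        assert p < 1e-6

    def test_oneway_anova_available(self, rng):
        f, p = oneway_anova({"a": rng.random(30), "b": rng.random(30)})
        assert f >= 0.0 and 0.0 <= p <= 1.0
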