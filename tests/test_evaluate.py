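import numpy as np
import pytest
from scipy import stats

from grsrisk.evaluate import (
    auc_mann_whitney,
    auc_rank,
    bootstrap_optimism,
    compare_auc,
    confusion_metrics,
    hosmer_lemeshow,
    metrics_at_cutoff,
    roc_points,
    split_validate,
    youden_cutoff_metrics,
)
from grsrisk.model import logistic_procedure
from grsrisk.presets import SMOKING_COUNTS
from grsrisk.synth import expanded_scores
from grsrisk.types import GrsError


def _informative(n, seed, shift=1.0):
    rng = np.random.default_rng(seed)
    status = rng.integers(0, 2, n)
    scores = rng.normal(0, 1, n) + shift * status
    return scores, status


class TestAucRank:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        status = np.r_[np.zeros(10), np.ones(10)].astype(int)
        assert auc_mann_whitney(scores, status) == 1.0

    def test_all_ties(self):
        status = np.r_[np.zeros(10), np.ones(10)].astype(int)
        assert auc_mann_whitney(np.ones(20), status) == 0.5

    def test_smoking_counts_value(self):
        scores, status = expanded_scores(SMOKING_COUNTS, {"never": 0, "light": 1, "heavy": 2})
        assert round(auc_mann_whitney(scores, status), 3) == 0.619

    def test_matches_pairwise_bruteforce(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 5, 60).astype(float)
        status = rng.integers(0, 2, 60)
        cases, ctrls = scores[status == 1], scores[status == 0]
        wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
        assert auc_mann_whitney(scores, status) == pytest.approx(
            wins / (len(cases) * len(ctrls)), rel=1e-12
        )

    def test_auc_equals_trapezoid_of_own_curve(self):
        scores, status = _informative(500, seed=1)
        auc = auc_mann_whitney(scores, status)
        curve = roc_points(scores, status)
        trapz = np.trapezoid(curve["tpr"], curve["fpr"])
        assert auc == pytest.approx(trapz, abs=1e-10)

    def test_monotone_transform_invariance(self):
        scores, status = _informative(400, seed=2)
        base = auc_mann_whitney(scores, status)
        assert auc_mann_whitney(np.exp(scores), status) == pytest.approx(base, abs=1e-12)
        assert auc_mann_whitney(3.0 * scores - 7.0, status) == pytest.approx(base, abs=1e-12)

    def test_bootstrap_ci_contains_estimate(self):
        scores, status = _informative(300, seed=3)
        r = auc_rank(scores, status, n_boot=300, seed=0)
        assert r.ci95[0] <= r.auc <= r.ci95[1]
        assert r.curve["fpr"].iloc[0] == 0 and r.curve["tpr"].iloc[-1] == 1

    def test_one_class_rejected(self):
        with pytest.raises(GrsError):
            auc_mann_whitney(np.ones(5), np.ones(5, dtype=int))


class TestCompareAuc:
    def test_identical_scores(self):
        scores, status = _informative(200, seed=4)
        delta, p = compare_auc(scores, scores, status, n_boot=200, seed=0)
        assert delta == 0.0
        assert p == pytest.approx(1.0)

    def test_monotone_transform_zero_delta(self):
        scores, status = _informative(200, seed=5)
        delta, _ = compare_auc(np.exp(scores), scores, status, n_boot=50, seed=0)
        assert delta == 0.0

    def test_informative_vs_noise(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            scores, status = _informative(2000, seed=seed, shift=0.8)
            noise = rng.normal(0, 1, 2000)
            _, p = compare_auc(scores, noise, status, n_boot=400, seed=seed)
            hits += p < 0.01
        assert hits >= 5 * 0.95 - 1  # all but at most one seed

    def test_delong_agrees_with_bootstrap_direction(self):
        scores, status = _informative(1500, seed=6, shift=0.8)
        rng = np.random.default_rng(6)
        noise = rng.normal(0, 1, 1500)
        d1, p1 = compare_auc(scores, noise, status, method="delong")
        assert d1 > 0 and p1 < 0.01

    def test_unpaired_rejected(self):
        with pytest.raises(GrsError):
            compare_auc(np.ones(5), np.ones(6), np.r_[np.zeros(3), np.ones(2)].astype(int))


class TestHosmerLemeshow:
    def test_exact_calibration_zero_statistic(self):
        # 10 probability levels; observed counts equal expected exactly
        probs, ys = [], []
        for k in range(1, 10):
            p = k / 10
            probs += [p] * 10
            ys += [1] * k + [0] * (10 - k)
        stat, p_val = hosmer_lemeshow(np.array(probs), np.array(ys))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p_val == pytest.approx(1.0)

    def test_halved_probabilities_detected(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.1, 0.9, 5000)
            y = (rng.random(5000) < p).astype(int)
            _, p_val = hosmer_lemeshow(p / 2.0, y)
            hits += p_val < 0.05
        assert hits >= 4

    def test_pvalues_uniform_under_well_specified_model(self):
        proc = logistic_procedure()
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(0, 1, 800)
            y = (rng.random(800) < 1 / (1 + np.exp(-(-0.3 + 0.8 * x)))).astype(int)
            fitted = proc(x[:, None], y)(x[:, None])
            _, p_val = hosmer_lemeshow(fitted, y)
            pvals.append(p_val)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_bad_groups_rejected(self):
        with pytest.raises(GrsError):
            hosmer_lemeshow(np.array([0.5, 0.5]), np.array([0, 1]), n_groups=1)
        with pytest.raises(GrsError):
            hosmer_lemeshow(np.full(100, 0.3), np.zeros(100, dtype=int))


class TestBootstrapOptimism:
    def test_fixed_rule_has_no_optimism(self):
        scores, status = _informative(2000, seed=7)

        def fixed_procedure(X, y):
            return lambda X_new: X_new[:, 0]

        r = bootstrap_optimism(scores[:, None], status, fixed_procedure, n_boot=200, seed=0)
        assert abs(r.optimism) < 0.01
        assert r.auc_corrected == pytest.approx(r.auc_apparent - r.optimism, abs=1e-12)

    def test_corrected_below_apparent_when_optimism_positive(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (400, 5))
        y = rng.integers(0, 2, 400)  # pure noise model overfits
        r = bootstrap_optimism(X, y, logistic_procedure(), n_boot=100, seed=1)
        assert r.optimism >= 0
        assert r.auc_corrected <= r.auc_apparent

    def test_invalid_b_rejected(self):
        with pytest.raises(GrsError):
            bootstrap_optimism(np.ones((4, 1)), np.array([0, 1, 0, 1]), logistic_procedure(), n_boot=0)


class TestSplitValidate:
    def test_null_model_near_chance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (4000, 2))
        y = rng.integers(0, 2, 4000)
        c_train, c_test = split_validate(X, y, logistic_procedure(), seed=0)
        assert abs(c_train - 0.5) < 0.03
        assert abs(c_test - 0.5) < 0.05

    def test_duplicated_halves_symmetry(self):
        scores, status = _informative(500, seed=10)
        X = np.r_[scores, scores][:, None]
        y = np.r_[status, status]
        # a 50/50 split of duplicated data refits on the same distribution
        c_train, c_test = split_validate(X, y, logistic_procedure(), train_fraction=0.5, seed=2)
        assert abs(c_train - c_test) < 0.05

    def test_bad_fraction_rejected(self):
        with pytest.raises(GrsError):
            split_validate(np.ones((4, 1)), np.array([0, 1, 0, 1]), logistic_procedure(), train_fraction=1.5)


class TestYoudenCutoff:
    def test_perfect_classifier(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        status = np.r_[np.zeros(10), np.ones(10)].astype(int)
        m = youden_cutoff_metrics(scores, status)
        assert (m.sensitivity, m.specificity, m.accuracy, m.ppv, m.npv) == (1, 1, 1, 1, 1)

    def test_scores_equal_status(self):
        status = np.r_[np.zeros(15), np.ones(5)].astype(int)
        m = youden_cutoff_metrics(status.astype(float), status)
        assert 0 < m.cutoff <= 1
        assert m.accuracy == 1.0

    def test_confusion_arithmetic_oracle(self):
        m = confusion_metrics(tp=90, fn=10, tn=80, fp=20)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.80)
        assert m.ppv == pytest.approx(0.818, abs=5e-4)
        assert m.npv == pytest.approx(0.889, abs=5e-4)
        assert m.accuracy == pytest.approx(0.85)

    def test_forced_cutoff_realizes_confusion(self):
        # 90 cases above 0.5, 10 below; 80 controls below, 20 above
        scores = np.r_[np.full(90, 0.9), np.full(10, 0.1), np.full(80, 0.2), np.full(20, 0.8)]
        status = np.r_[np.ones(100), np.zeros(100)].astype(int)
        m = metrics_at_cutoff(scores, status, 0.5)
        assert (m.tp, m.fn, m.tn, m.fp) == (90, 10, 80, 20)

    def test_tie_broken_toward_higher_specificity(self):
        # two cutoffs tie on J; the higher threshold (higher spec) must win
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        status = np.array([0, 1, 0, 1])
        m = youden_cutoff_metrics(scores, status)
        brute = []
        for t in np.unique(scores):
            mm = metrics_at_cutoff(scores, status, t)
            brute.append((mm.sensitivity + mm.specificity, t))
        best_j = max(j for j, _ in brute)
        best_t = max(t for j, t in brute if j == best_j)
        assert m.cutoff == best_t

    def test_matches_bruteforce_scan(self):
        scores, status = _informative(300, seed=11)
        m = youden_cutoff_metrics(scores, status)
        brute_best = max(
            (metrics_at_cutoff(scores, status, t).sensitivity
             + metrics_at_cutoff(scores, status, t).specificity)
            for t in np.unique(scores)
        )
        assert m.sensitivity + m.specificity == pytest.approx(brute_best, abs=1e-12)
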