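import numpy as np
import pandas as pd
import pytest

import oracles
from habitatrad.evaluation import (
    ALGORITHMS,
    EvalReport,
    ModelSpec,
    compare_models,
    crossvalidate,
    decision_curve,
    evaluate_scores,
    fit_predict,
    hosmer_lemeshow,
    roc_auc,
    stratified_split,
)


def _separable(n=40, rng=None):
    rng = rng or np.random.default_rng(0)
    y = np.tile([0, 1], n // 2)
    X = np.column_stack([y + 0.01 * rng.normal(size=n),
                         rng.normal(size=n)])
    return X, y


class TestFitPredict:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_training_auc_is_one(self, algorithm):
        X, y = _separable(n=80)
        spec = ModelSpec(algorithm=algorithm, seed=0)
        scores = fit_predict(spec, X, y, X)
        auc, _ = roc_auc(scores, y)
        assert auc == 1.0
        assert ((scores >= 0) & (scores <= 1)).all()

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_deterministic_under_seed(self, algorithm):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, 60)
        spec = ModelSpec(algorithm=algorithm, seed=5)
        a = fit_predict(spec, X, y, X)
        b = fit_predict(spec, X, y, X)
        assert np.array_equal(a, b)

    def test_shuffled_labels_give_chance_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X_train = rng.normal(size=(150, 10))
            y_train = rng.permutation(np.tile([0, 1], 75))
            X_test = rng.normal(size=(80, 10))
            y_test = rng.permutation(np.tile([0, 1], 40))
            spec = ModelSpec(algorithm="logistic_regression", seed=seed)
            scores = fit_predict(spec, X_train, y_train, X_test)
            aucs.append(roc_auc(scores, y_test)[0])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="single class"):
            fit_predict(ModelSpec(), X, np.zeros(10), X)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(algorithm="svm")


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc(np.full(10, 0.5), np.tile([0, 1], 5))
        assert auc == 0.5

    def test_ten_point_example_matches_bruteforce(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.65, 0.2, 0.9, 0.5, 0.3])
        labels = np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0])
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(oracles.auc_bruteforce(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_inputs_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        scores = np.round(rng.uniform(size=n), 2)  # force ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(oracles.auc_bruteforce(scores, labels), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.2, 0.4]), np.array([1, 1]))

    def test_bootstrap_ci_brackets_estimate(self, rng):
        scores = rng.uniform(size=100)
        labels = (scores + rng.normal(0, 0.3, 100) > 0.5).astype(int)
        auc, ci = roc_auc(scores, labels, n_boot=200, seed=0)
        assert ci[0] <= auc <= ci[1]


class TestHosmerLemeshow:
    def test_perfect_bin_agreement_is_zero(self):
        probs = np.full(20, 0.5)
        labels = np.tile([0, 1], 10)
        stat, df, p = hosmer_lemeshow(probs, labels)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_summed_oracle(self):
        rng = np.random.default_rng(8)
        probs = rng.uniform(0.05, 0.95, 20)
        labels = rng.binomial(1, probs)
        stat, df, _ = hosmer_lemeshow(probs, labels, n_bins=5)
        ref_stat, ref_df = oracles.hosmer_lemeshow_oracle(probs, labels, n_bins=5)
        assert stat == pytest.approx(ref_stat, abs=1e-9)
        assert df == ref_df

    def test_type_one_error_near_nominal(self):
        # under a correctly specified logistic model, the statistic on the
        # model's own fitted probabilities is ~ chi-square(G-2): rejection
        # rate should sit at the nominal alpha
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(17)
        rejections = 0
        reps = 500
        for _ in range(reps):
            X = rng.normal(size=(200, 2))
            true_p = 1 / (1 + np.exp(-(0.5 * X[:, 0] - 0.8 * X[:, 1])))
            labels = rng.binomial(1, true_p)
            probs = (
                LogisticRegression(max_iter=1000).fit(X, labels)
                .predict_proba(X)[:, 1]
            )
            _, _, p = hosmer_lemeshow(probs, labels)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.03

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.array([0.5] * 5), np.array([1, 0, 1, 0, 1]))


class TestDecisionCurve:
    def test_treat_none_is_zero_everywhere(self, rng):
        probs = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50)
        dca = decision_curve(probs, labels)
        assert (dca["treat_none"] == 0.0).all()

    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        dca = decision_curve(labels.astype(float), labels)
        assert np.allclose(dca["net_benefit"], labels.mean())

    def test_treat_all_formula_exact(self, rng):
        labels = rng.integers(0, 2, 40)
        probs = rng.uniform(size=40)
        pi = labels.mean()
        dca = decision_curve(probs, labels, thresholds=np.array([0.1, 0.25, 0.5]))
        expected = pi - (1 - pi) * dca["threshold"] / (1 - dca["threshold"])
        assert np.allclose(dca["treat_all"], expected)

    def test_eight_point_example_matches_confusion_oracle(self):
        probs = np.array([0.9, 0.8, 0.3, 0.6, 0.2, 0.1, 0.7, 0.4])
        labels = np.array([1, 1, 0, 1, 0, 0, 0, 1])
        dca = decision_curve(probs, labels, thresholds=np.array([0.25]))
        assert dca["net_benefit"].iloc[0] == pytest.approx(
            oracles.net_benefit_oracle(probs, labels, 0.25), abs=1e-12
        )

    def test_net_benefit_never_exceeds_prevalence(self, rng):
        probs = rng.uniform(size=60)
        labels = rng.integers(0, 2, 60)
        dca = decision_curve(probs, labels)
        assert (dca["net_benefit"] <= labels.mean() + 1e-12).all()

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            decision_curve(np.array([0.5]), np.array([1]),
                           thresholds=np.array([0.0, 0.5]))


class TestCrossValidation:
    def test_separable_data_perfect_mean_auc(self):
        # one fold per class-pair: smallest folds where AUC is defined
        X, y = _separable(n=20)
        spec = ModelSpec(algorithm="logistic_regression", seed=0)
        _, mean_auc, _ = crossvalidate(spec, X, y, n_folds=10, seed=0)
        assert mean_auc == 1.0

    def test_fold_assignment_reproducible(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = np.tile([0, 1], 20)
        spec = ModelSpec(algorithm="logistic_regression", seed=0)
        r1, m1, s1 = crossvalidate(spec, X, y, n_folds=5, seed=9)
        r2, m2, s2 = crossvalidate(spec, X, y, n_folds=5, seed=9)
        assert m1 == m2 and s1 == s2
        assert [r.auc for r in r1] == [r.auc for r in r2]

    def test_impossible_stratification(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="stratification"):
            crossvalidate(ModelSpec(), X, y, n_folds=5)

    def test_stratified_split_preserves_balance(self):
        y = np.tile([0, 1], 50)
        tr, te = stratified_split(np.arange(100), y, test_size=0.3, seed=0)
        assert len(te) == 30
        assert y[te].mean() == pytest.approx(0.5)
        assert set(tr) | set(te) == set(range(100))


def _mk_report(algorithm, auc, dataset="test"):
    return EvalReport(
        dataset=dataset, algorithm=algorithm, auc=auc, auc_ci=None,
        roc_points=pd.DataFrame(), calibration=pd.DataFrame(),
        hl_statistic=0.0, hl_df=8, hl_pvalue=1.0, dca=pd.DataFrame(),
        confusion_at_half={},
    )


class TestCompareModels:
    def test_higher_auc_ranks_first(self):
        df = compare_models([_mk_report("a", 0.79), _mk_report("b", 0.82)])
        assert df.iloc[0]["algorithm"] == "b"

    def test_ties_resolved_by_name(self):
        df = compare_models([_mk_report("zeta", 0.8), _mk_report("alpha", 0.8)])
        assert list(df["algorithm"]) == ["alpha", "zeta"]

    def test_ranking_invariant_to_input_order(self):
        reports = [_mk_report(a, auc) for a, auc in
                   [("a", 0.7), ("b", 0.9), ("c", 0.8)]]
        d1 = compare_models(reports)
        d2 = compare_models(list(reversed(reports)))
        assert list(d1["algorithm"]) == list(d2["algorithm"])


class TestEvaluateScores:
    def test_report_is_internally_consistent(self, rng):
        probs = rng.uniform(size=80)
        labels = rng.integers(0, 2, 80)
        rep = evaluate_scores(probs, labels, n_boot=50)
        assert 0.0 <= rep.auc <= 1.0
        assert rep.calibration["n"].sum() == 80
        conf = rep.confusion_at_half
        assert sum(conf.values()) == 80
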