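import numpy as np
import pandas as pd
import pytest

import oracles
from habitatrad.selection import (
    distribution_filter,
    icc,
    icc_filter,
    lasso_select,
    pearson_prune,
    run_selection,
)


class TestIcc:
    def test_perfect_agreement_is_one(self, rng):
        x = rng.normal(size=30)
        assert icc(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_permuted_raters_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=1000)
        perm = rng.permutation(x)
        assert abs(icc(np.column_stack([x, perm]))) < 0.1

    def test_matches_anova_oracle_and_pingouin(self):
        x = np.array([
            [9.0, 2.0], [4.5, 4.0], [7.0, 6.5], [5.0, 5.5],
            [8.5, 7.0], [6.0, 8.0],
        ])
        mine = icc(x)
        assert mine == pytest.approx(oracles.icc21_anova(x), abs=1e-12)
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(6), 2),
            "rater": np.tile([0, 1], 6),
            "score": x.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        # ICC(A,1): absolute agreement, single rater == ICC(2,1)
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert mine == pytest.approx(icc2, abs=1e-9)

    def test_zero_variance_undefined(self):
        assert np.isnan(icc(np.full((5, 2), 3.0)))


class TestIccFilter:
    def _designs(self, rng):
        good = rng.normal(size=30)
        noisy = rng.normal(size=30)
        retest = {
            "stable": np.column_stack([good, good]),
            "unstable": np.column_stack([noisy, rng.normal(size=30)]),
            "flat": np.full((30, 2), 1.0),
        }
        inter = {k: v.copy() for k, v in retest.items()}
        return retest, inter

    def test_min_rule_and_degenerate_drop(self, rng):
        retest, inter = self._designs(rng)
        survivors, values = icc_filter(retest, inter, threshold=0.85)
        assert "stable" in survivors
        assert "unstable" not in survivors
        assert "flat" not in survivors  # undefined ICC fails
        assert values["stable"][0] == pytest.approx(1.0)

    def test_vacuous_threshold_keeps_all_defined(self, rng):
        retest, inter = self._designs(rng)
        survivors, _ = icc_filter(retest, inter, threshold=-1.0)
        assert set(survivors) == {"stable", "unstable"}

    def test_raising_threshold_never_adds_survivors(self, rng):
        retest, inter = self._designs(rng)
        prev = None
        for thr in (-1.0, 0.0, 0.5, 0.85, 0.99):
            cur, _ = icc_filter(retest, inter, threshold=thr)
            if prev is not None:
                assert set(cur) <= set(prev)
            prev = cur


class TestDistributionFilter:
    def test_normal_feature_passes_at_nominal_rate(self):
        # type-I error of the Shapiro screen ~ alpha
        rng = np.random.default_rng(11)
        passed = 0
        reps = 500
        for _ in range(reps):
            table = pd.DataFrame({"f": rng.normal(size=100)})
            survivors, _ = distribution_filter(table, alpha=0.05)
            passed += "f" in survivors
        assert abs(passed / reps - 0.95) < 0.03

    def test_lognormal_feature_rejected(self):
        rng = np.random.default_rng(12)
        removed = 0
        reps = 200
        for _ in range(reps):
            table = pd.DataFrame({"f": np.exp(rng.normal(size=100))})
            survivors, _ = distribution_filter(table, alpha=0.05)
            removed += "f" not in survivors
        assert removed / reps >= 0.95

    def test_alpha_zero_keeps_all_nondegenerate(self, rng):
        table = pd.DataFrame({
            "skewed": np.exp(rng.normal(size=50)),
            "normal": rng.normal(size=50),
            "flat": np.ones(50),
        })
        survivors, _ = distribution_filter(table, alpha=0.0)
        assert set(survivors) == {"skewed", "normal"}

    def test_t_fit_mode_accepts_heavy_tails(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame({"t3": rng.standard_t(3, size=200)})
        survivors, _ = distribution_filter(table, alpha=0.05, mode="t_fit")
        assert "t3" in survivors

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            distribution_filter(pd.DataFrame({"f": np.arange(5.0)}))


class TestPearsonPrune:
    def test_duplicate_column_keeps_exactly_one(self, rng):
        x = rng.normal(size=40)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=40)})
        survivors, dropped = pearson_prune(table, 0.9)
        assert len({"a", "b"} & set(survivors)) == 1
        assert "c" in survivors
        assert len(dropped) == 1

    def test_orthogonal_features_all_survive(self):
        n = 60
        t = np.arange(n)
        table = pd.DataFrame({
            "s1": np.sin(2 * np.pi * t / n),
            "s2": np.cos(2 * np.pi * t / n),
            "s3": np.sin(4 * np.pi * t / n),
        })
        survivors, dropped = pearson_prune(table, 0.9)
        assert set(survivors) == {"s1", "s2", "s3"} and not dropped

    def test_matches_bruteforce_oracle(self, rng):
        base = rng.normal(size=50)
        table = pd.DataFrame({
            "f0": base,
            "f1": base + 0.05 * rng.normal(size=50),
            "f2": base + 0.10 * rng.normal(size=50),
            "f3": rng.normal(size=50),
            "f4": -base + 0.05 * rng.normal(size=50),
        })
        survivors, _ = pearson_prune(table, 0.8)
        assert survivors == oracles.pearson_prune_oracle(table, 0.8)
        # no surviving pair above the threshold
        corr = table[survivors].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.8


class TestLasso:
    def test_full_shrinkage_at_huge_lambda(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, 50)
        report = lasso_select(X, y, lambda_grid=np.array([1e6, 1e5]), seed=0)
        assert report.coefficients == {}
        assert report.chosen_lambda in (1e6, 1e5)

    def test_oracle_support_noise_free(self, rng):
        n = 60
        y = np.tile([0, 1], n // 2)
        X = pd.DataFrame({
            "signal": y.astype(float),
            "n1": rng.normal(size=n),
            "n2": rng.normal(size=n),
        })
        report = lasso_select(X, y, seed=0)
        assert "signal" in report.coefficients
        assert report.coefficients["signal"] > 0

    def test_planted_recovery_five_informative(self):
        # 5 informative / 95 noise, n=120, 1 SD effect; median over 20 seeds
        recovered, false_pos = [], []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            y = np.tile([0, 1], 60)
            X = rng.normal(size=(120, 100))
            X[:, :5] += y[:, None] * 1.0
            table = pd.DataFrame(X, columns=[f"f{i:03d}" for i in range(100)])
            report = lasso_select(table, y, seed=seed)
            sel = set(report.coefficients)
            recovered.append(len(sel & {f"f{i:03d}" for i in range(5)}))
            false_pos.append(len(sel - {f"f{i:03d}" for i in range(5)}))
        assert np.median(recovered) >= 4
        assert np.median(false_pos) <= 5

    def test_all_constant_rejected(self):
        X = pd.DataFrame(np.ones((20, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            lasso_select(X, np.tile([0, 1], 10))

    def test_chosen_lambda_invariant_to_feature_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 10)),
                         columns=[f"f{i}" for i in range(10)])
        y = (X["f0"] + 0.5 * rng.normal(size=80) > 0).astype(int)
        grid = np.logspace(-0.5, -3, 40)
        a = lasso_select(X, y, lambda_grid=grid, seed=1)
        b = lasso_select(X[list(reversed(X.columns))], y, lambda_grid=grid, seed=1)
        assert a.chosen_lambda == b.chosen_lambda
        assert a.coefficients == pytest.approx(b.coefficients)


class TestRunSelection:
    def test_stages_nested_and_deterministic(self, rng):
        n = 80
        y = np.tile([0, 1], n // 2)
        X = pd.DataFrame(rng.normal(size=(n, 30)),
                         columns=[f"f{i:02d}" for i in range(30)])
        X["f00"] += y * 1.5
        X["f29"] = X["f00"] * 1.001 + 1e-4  # near-duplicate for pruning
        X["f28"] = np.exp(X["f28"] * 2)  # skewed, should fail the screen
        rep1 = run_selection(X, y, seed=4)
        rep2 = run_selection(X, y, seed=4)
        rep1.assert_nested()
        assert rep1.stages.keys() == rep2.stages.keys()
        assert rep1.selected == rep2.selected
        assert "f28" not in rep1.stages["distribution"]
        pearson_set = set(rep1.stages["pearson"])
        assert len({"f00", "f29"} & pearson_set) <= 1
        assert rep1.chosen_lambda in rep1.lambda_grid
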