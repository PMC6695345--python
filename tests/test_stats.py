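import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from habitrl import stats
from habitrl.stats import (ancova_habit_bias, correlation_with_fisher_compare,
                           fisher_z_compare, habit_bias, stepwise_regression)


def _dev_frame(go_dev, go_val, subject=0, group="control"):
    rows = []
    for i, g in enumerate(go_dev):
        rows.append((subject, group, "devaluation", 0, i, 0, 2 if g else 3,
                     None, 1))
    for i, g in enumerate(go_val):
        rows.append((subject, group, "devaluation", 0, 100 + i, 1,
                     2 if g else 3, None, 0))
    return pd.DataFrame(rows, columns=["subject_id", "group", "phase", "block",
                                       "trial", "stimulus_id", "response",
                                       "reward", "devalued_flag"])


class TestHabitBias:
    def test_direct_subtraction(self):
        df = _dev_frame([1, 1, 0, 0, 0], [1] * 9 + [0])
        rec = habit_bias(df)
        assert rec.habit_bias == pytest.approx(0.4 - 0.9)

    def test_equal_rates_give_zero(self):
        df = _dev_frame([1, 0] * 5, [1, 0] * 5)
        assert habit_bias(df).habit_bias == 0.0

    def test_all_go_responder_saturates_at_zero(self):
        df = _dev_frame([1] * 6, [1] * 6)
        rec = habit_bias(df)
        assert rec.p_respond_devalued == rec.p_respond_valued == 1.0
        assert rec.habit_bias == 0.0

    def test_order_invariance(self):
        df = _dev_frame([1, 1, 0, 0], [1, 0, 1, 0])
        shuffled = df.sample(frac=1, random_state=0)
        assert habit_bias(df).habit_bias == habit_bias(shuffled).habit_bias

    def test_missing_class_rejected(self):
        df = _dev_frame([1, 0], [])
        with pytest.raises(ValueError):
            habit_bias(df)


class TestStepwise:
    def test_perfect_predictor_selected(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((80, 3)),
                         columns=["a", "b", "c"])
        y = X["b"].to_numpy()
        res = stepwise_regression(y, X)
        assert res.selected == ["b"]
        assert res.r_squared == pytest.approx(1.0)

    def test_group_effect_calibrated_r2(self):
        """Outcome = 0.4 * group + noise sized for R^2 ~= 0.12 at n = 123:
        group enters first and R^2 lands near 0.12 across replicates."""
        rng = np.random.default_rng(1)
        r2s, first = [], []
        group = np.repeat([0.0, 1.0], [55, 68])
        sigma = np.sqrt(0.4 ** 2 * np.var(group) * (1 / 0.12 - 1))
        for _ in range(50):
            noise = rng.standard_normal(123) * sigma
            y = 0.4 * group + noise
            X = pd.DataFrame({"group": group,
                              "alpha": rng.standard_normal(123),
                              "beta": rng.standard_normal(123)})
            res = stepwise_regression(y, X)
            if res.entry_order:
                first.append(res.entry_order[0])
            r2s.append(res.r_squared)
        assert np.mean([f == "group" for f in first]) > 0.9
        assert np.mean(r2s) == pytest.approx(0.12, abs=0.06)

    def test_null_selection_control(self):
        """Pure-noise outcomes: with 4 candidates at entry p = 0.05, the
        selected set is empty in the large majority of replicates."""
        rng = np.random.default_rng(2)
        empty = 0
        for _ in range(200):
            X = pd.DataFrame(rng.standard_normal((60, 4)),
                             columns=list("abcd"))
            y = rng.standard_normal(60)
            if not stepwise_regression(y, X).selected:
                empty += 1
        # familywise: P(no entry) ~ (1 - 0.05)^4 ~ 0.81; allow slack
        assert empty / 200 > 0.7

    def test_reduces_to_full_ols_with_vacuous_thresholds(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        y = (X @ [0.5, -0.3, 0.2]).to_numpy() + rng.standard_normal(50)
        res = stepwise_regression(y, X, entry_p=1.0, removal_p=1.0)
        assert set(res.selected) == {"a", "b", "c"}
        ys = (y - y.mean()) / y.std()
        Xs = (X - X.mean()) / X.std()
        full = sm.OLS(ys, sm.add_constant(Xs)).fit()
        for c in "abc":
            assert res.coefficients[c] == pytest.approx(full.params[c], abs=1e-12)

    def test_constant_predictor_rejected(self):
        X = pd.DataFrame({"a": np.ones(30), "b": np.arange(30.0)})
        with pytest.raises(ValueError):
            stepwise_regression(np.arange(30.0), X)


class TestAncova:
    def test_null_type_one_error_rate(self):
        """Equal group means: the group F-test rejects at ~5%."""
        rng = np.random.default_rng(4)
        rejections = 0
        n_sim = 400
        group = np.repeat(["a", "b"], 30)
        for _ in range(n_sim):
            y = rng.standard_normal(60)
            cov = pd.DataFrame({"c": rng.standard_normal(60)})
            res = ancova_habit_bias(y, group, cov)
            rejections += res.p_group < 0.05
        rate = rejections / n_sim
        assert 0.02 < rate < 0.09

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(5)
        group = np.repeat([0, 1], 40)
        fs = []
        for effect in (0.0, 0.5, 1.0):
            f_acc = []
            for _ in range(40):
                y = effect * group + rng.standard_normal(80)
                cov = pd.DataFrame({"c": rng.standard_normal(80)})
                f_acc.append(ancova_habit_bias(y, group, cov).f_group)
            fs.append(np.mean(f_acc))
        assert fs[0] < fs[1] < fs[2]

    def test_outcome_as_covariate_flagged(self):
        y = np.random.default_rng(6).standard_normal(40)
        group = np.repeat(["a", "b"], 20)
        with pytest.raises(ValueError):
            ancova_habit_bias(y, group, pd.DataFrame({"c": y}))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ancova_habit_bias(np.zeros(10), np.repeat("a", 10), None)


class TestFisherZ:
    def test_identical_correlations(self):
        res = fisher_z_compare(0.3, 50, 0.3, 40)
        assert res.z == 0.0
        assert res.p_one_tailed == pytest.approx(0.5)

    def test_published_comparison_values(self):
        """r = .406 (n=43) vs r = .070 (n=40) gives Z ~= 1.56 one-tailed."""
        res = fisher_z_compare(0.406, 43, 0.070, 40)
        assert res.z == pytest.approx(1.56, abs=0.03)
        assert res.p_one_tailed == pytest.approx(0.059, abs=0.005)

    def test_extreme_samples_give_large_z(self):
        x = np.arange(10.0)
        res = correlation_with_fisher_compare(x, x + np.random.default_rng(0)
                                              .normal(0, 0.01, 10),
                                              x, -x + np.random.default_rng(1)
                                              .normal(0, 0.01, 10))
        assert res.z > 3
        assert res.p_one_tailed < 0.001

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_with_fisher_compare(np.ones(10), np.arange(10.0),
                                            np.arange(10.0), np.arange(10.0))

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.1, 40)


def test_per_block_option_matches_pooled_on_balanced_blocks():
    # balanced block sizes: per-block averaging equals pooling
    frames = []
    for b in range(3):
        f = _dev_frame([1, 0, 1, 0], [1, 1, 1, 0])
        f["block"] = b
        f["trial"] += 200 * b
        frames.append(f)
    df = pd.concat(frames, ignore_index=True)
    pooled = habit_bias(df).habit_bias
    blocked = habit_bias(df, per_block=True).habit_bias
    assert blocked == pytest.approx(pooled)
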