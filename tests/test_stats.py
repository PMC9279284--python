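import numpy as np
import pandas as pd
import pytest

from lakeburial.stats import (
    compact_letters,
    fit_forest_exponential,
    fit_linear,
    fit_quadratic,
    fit_temperature_models,
    group_comparison,
    select_buffer,
    variance_curve,
)


class TestOlsFits:
    def test_linear_exact_recovery(self):
        x = np.arange(0.0, 31.0, 2.5)
        fit = fit_linear(x, 4.23 * x + 15.15)
        assert fit.params["x"] == pytest.approx(4.23, abs=1e-10)
        assert fit.params["intercept"] == pytest.approx(15.15, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_quadratic_exact_recovery(self):
        x = np.arange(-5.0, 30.0, 2.0)
        fit = fit_quadratic(x, 82.93 + 4.01 * x + 0.08 * x**2)
        assert fit.params["intercept"] == pytest.approx(82.93, abs=1e-9)
        assert fit.params["x"] == pytest.approx(4.01, abs=1e-10)
        assert fit.params["x2"] == pytest.approx(0.08, abs=1e-11)

    def test_constant_response_zero_slope_zero_r2(self):
        x = np.arange(10.0)
        fit = fit_linear(x, np.full(10, 7.0))
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 30, 40)
        y = 3.0 + 2.0 * x + rng.normal(0, 5, 40)
        fit = fit_linear(x, y)
        resid = y - fit.predict(x)
        assert abs(resid.sum()) < 1e-8
        assert abs((resid * x).sum()) < 1e-6

    def test_collinear_design_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            fit_quadratic(np.full(6, 2.0), np.arange(6.0))

    def test_temperature_models_wrapper(self):
        t = np.arange(-5.0, 28.0, 1.5)
        lakes = pd.DataFrame({"annual_temp": t, "burial": 4.23 * t + 15.15})
        forest = pd.DataFrame(
            {"annual_temp": t, "oc_accumulation": 82.93 + 4.01 * t + 0.08 * t**2}
        )
        lake_fit, forest_fit = fit_temperature_models(lakes, forest)
        assert lake_fit.predict(0.0) == pytest.approx(15.15)
        assert forest_fit.predict(0.0) == pytest.approx(82.93)


class TestExponentialFit:
    def test_noiseless_recovery_to_four_significant_digits(self):
        x = np.arange(0.0, 101.0, 10.0)
        fit = fit_forest_exponential(x, 56.21 * np.exp(0.01608 * x))
        assert fit.params["a"] == pytest.approx(56.21, rel=1e-4)
        assert fit.params["b"] == pytest.approx(0.01608, rel=1e-4)

    def test_constant_data_gives_mean(self):
        x = np.arange(0.0, 50.0, 10.0)
        fit = fit_forest_exponential(x, np.full(5, 42.0))
        assert fit.params["a"] == pytest.approx(42.0)
        assert fit.params["b"] == pytest.approx(0.0, abs=1e-12)

    def test_loglinear_and_nls_agree_on_noiseless_data(self):
        x = np.arange(0.0, 101.0, 5.0)
        y = 30.0 * np.exp(0.02 * x)
        b_ll, loga = np.polyfit(x, np.log(y), 1)
        fit = fit_forest_exponential(x, y)
        assert fit.params["a"] == pytest.approx(np.exp(loga), rel=1e-8)
        assert fit.params["b"] == pytest.approx(b_ll, rel=1e-8)

    def test_bias_vanishes_as_noise_vanishes(self):
        x = np.arange(0.0, 101.0, 5.0)
        a, b = 56.21, 0.01608
        rng = np.random.default_rng(10)
        bias = []
        for cv in (0.3, 0.02, 0.0):
            errs = []
            for _ in range(40):
                y = a * np.exp(b * x)
                if cv:
                    y = y * np.exp(rng.normal(0, cv, x.size) - 0.5 * cv**2)
                f = fit_forest_exponential(x, y)
                errs.append(abs(f.params["a"] - a) / a + abs(f.params["b"] - b) / b)
            bias.append(np.mean(errs))
        assert bias[0] > bias[1] > bias[2]
        assert bias[2] < 1e-8

    def test_nonpositive_burial_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            fit_forest_exponential([0.0, 10.0, 20.0], [1.0, -2.0, 3.0])


class TestGroupComparison:
    def test_identical_groups_share_one_letter(self):
        data = np.array([10.0, 12.0, 11.0, 13.0, 9.0])
        cmp = group_comparison({"a": data, "b": data, "c": data})
        assert set(cmp.letters.values()) == {"a"}
        assert cmp.anova_p > 0.99

    def test_widely_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        g1 = np.exp(rng.normal(2.0, 0.1, 12))
        g2 = np.exp(rng.normal(4.0, 0.1, 12))  # ~20 pooled SD apart on logs
        cmp = group_comparison({"low": g1, "high": g2})
        assert not set(cmp.letters["low"]) & set(cmp.letters["high"])
        assert cmp.anova_p < 1e-6 and cmp.kruskal_p < 0.001

    def test_letters_partition_consistency(self):
        rng = np.random.default_rng(21)
        groups = {
            f"g{i}": np.exp(rng.normal(mu, 0.4, 10))
            for i, mu in enumerate([2.0, 2.1, 2.6, 3.6])
        }
        cmp = group_comparison(groups)
        rejected = {
            frozenset((r["group1"], r["group2"]))
            for _, r in cmp.tukey.iterrows()
            if bool(r["reject"])
        }
        for a in groups:
            for b in groups:
                if a >= b:
                    continue
                share = bool(set(cmp.letters[a]) & set(cmp.letters[b]))
                assert share == (frozenset((a, b)) not in rejected)

    def test_small_groups_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="excluded"):
            cmp = group_comparison(
                {
                    "ok1": rng.lognormal(3, 0.5, 8),
                    "ok2": rng.lognormal(3.5, 0.5, 8),
                    "tiny": np.array([5.0]),
                }
            )
        assert cmp.excluded == ("tiny",)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError, match="log"):
            group_comparison({"a": np.array([1.0, -1.0]), "b": np.array([2.0, 3.0])})


class TestCompactLetters:
    def test_no_differences_single_letter(self):
        assert set(compact_letters(["a", "b", "c"], []).values()) == {"a"}

    def test_chain_structure(self):
        # a != c but b bridges both
        letters = compact_letters(["a", "b", "c"], [("a", "c")])
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])

    def test_all_pairs_different(self):
        letters = compact_letters(["a", "b", "c"], [("a", "b"), ("a", "c"), ("b", "c")])
        assert len({v for v in letters.values()}) == 3


class TestBufferSelection:
    def test_argmax_r2(self):
        fits = {
            3.0: fit_linear([0, 1, 2, 3], [0.0, 1.0, 1.0, 2.0]),
            6.0: fit_linear([0, 1, 2, 3], [0.0, 1.0, 2.0, 3.0]),
            12.0: fit_linear([0, 1, 2, 3], [0.5, 1.0, 1.2, 2.5]),
        }
        assert select_buffer(fits) == 6.0

    def test_single_buffer(self):
        fits = {4.0: fit_linear([0, 1, 2], [0.0, 1.0, 2.5])}
        assert select_buffer(fits) == 4.0

    def test_tie_breaks_toward_smaller_buffer(self):
        perfect = fit_linear([0, 1, 2, 3], [0.0, 2.0, 4.0, 6.0])
        assert select_buffer({12.0: perfect, 6.0: perfect}) == 6.0


class TestVarianceCurve:
    def test_full_sample_reproduces_variance(self):
        rng = np.random.default_rng(6)
        rates = rng.lognormal(3, 0.6, 30)
        curve = variance_curve(rates, [30], reps=5, seed=1)
        assert curve["mean_variance"].iloc[0] == pytest.approx(np.var(rates, ddof=1))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        rates = rng.lognormal(3, 0.6, 40)
        c1 = variance_curve(rates, [5, 10, 20], reps=50, seed=3)
        c2 = variance_curve(rates, [5, 10, 20], reps=50, seed=3)
        pd.testing.assert_frame_equal(c1, c2)

    def test_iid_curve_is_flat_within_mc_error(self):
        # E[sample variance] = sigma^2 at every n for i.i.d. data
        rng = np.random.default_rng(9)
        rates = rng.normal(100, 10, 200)
        curve = variance_curve(rates, [10, 50, 150], reps=400, seed=4)
        v = curve["mean_variance"]
        assert v.max() / v.min() < 1.15

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError):
            variance_curve(np.arange(10.0), [11], reps=2, seed=0)
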