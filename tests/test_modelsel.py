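"""Gaussian fitters, AICc selection, averaging and RVI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import isoniche as iso
from isoniche.modelsel import _profiled_loglik, _design


class TestStandardize2SD:
    def test_two_point_hand_case(self):
        out = iso.standardize_2sd([0.0, 2.0])
        assert out == pytest.approx([-1 / (2 * np.sqrt(2)), 1 / (2 * np.sqrt(2))])

    def test_output_sd_is_half(self, rng):
        out = iso.standardize_2sd(rng.normal(10, 3, 200))
        assert out.std(ddof=1) == pytest.approx(0.5)

    def test_constant_column_rejected(self):
        with pytest.raises(iso.DataError):
            iso.standardize_2sd([1.0, 1.0, 1.0])

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10 ** 6),
           a=st.floats(-100, 100),
           b=st.floats(min_value=0.01, max_value=100))
    def test_affine_invariance(self, seed, a, b):
        x = np.random.default_rng(seed).normal(size=30)
        base = iso.standardize_2sd(x)
        np.testing.assert_allclose(iso.standardize_2sd(a + b * x), base, atol=1e-9)
        np.testing.assert_allclose(iso.standardize_2sd(a - b * x), -base, atol=1e-9)


class TestFitLinear:
    def test_noiseless_line_flagged_perfect(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 + 3.0 * df["x"]
        fit = iso.fit_linear(df, "y", ["x"])
        assert fit.r2_marginal == pytest.approx(1.0)
        assert fit.extra["perfect_fit"]

    def test_slope_recovered_within_three_se(self, rng):
        x = rng.normal(size=120)
        df = pd.DataFrame({"x": x, "y": 2.0 * x + rng.normal(0, 1, 120)})
        fit = iso.fit_linear(df, "y", ["x"])
        b, se = fit.coefficients["x"]
        assert abs(b - 2.0) < 3 * se

    def test_intercept_only_loglik_closed_form(self, rng):
        y = rng.normal(5, 2, 60)
        df = pd.DataFrame({"y": y})
        fit = iso.fit_linear(df, "y", [])
        s2 = y.var(ddof=0)
        assert fit.loglik == pytest.approx(
            -0.5 * 60 * (np.log(2 * np.pi * s2) + 1), rel=1e-12)
        assert fit.k == 2

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm
        x = rng.normal(size=(80, 2))
        y = 1 + x @ [0.5, -0.3] + rng.normal(0, 0.7, 80)
        df = pd.DataFrame({"y": y, "a": x[:, 0], "b": x[:, 1]})
        fit = iso.fit_linear(df, "y", ["a", "b", "a:b"])
        res = sm.OLS(y, sm.add_constant(
            np.column_stack([x, x[:, 0] * x[:, 1]]))).fit()
        assert fit.loglik == pytest.approx(res.llf, abs=1e-8)
        assert fit.coefficients["a"][0] == pytest.approx(res.params[1], abs=1e-10)
        assert fit.coefficients["a"][1] == pytest.approx(res.bse[1], rel=1e-8)

    def test_rank_deficiency_names_aliased_term(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"y": rng.normal(size=50), "a": x, "b": 2 * x})
        with pytest.raises(iso.DataError, match="aliased"):
            iso.fit_linear(df, "y", ["a", "b"])


def _grouped_data(seed, n_groups=9, group_size=10, group_sd=0.5, resid_sd=1.0,
                  slope=0.5):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), group_size)
    x = rng.normal(size=n_groups * group_size)
    y = 1.0 + slope * x + rng.normal(0, group_sd, n_groups)[g] \
        + rng.normal(0, resid_sd, n_groups * group_size)
    return pd.DataFrame({"y": y, "x": x, "site": g})


class TestRandomIntercept:
    def test_zero_between_variance_collapses_to_ols(self):
        df = _grouped_data(0, group_sd=0.0)
        lmm = iso.fit_random_intercept(df, "y", ["x"], "site", method="ML")
        ols = iso.fit_linear(df, "y", ["x"])
        # boundary fit: same profiled likelihood as plain least squares
        assert lmm.loglik <= ols.loglik + 1e-10
        assert abs(lmm.loglik - ols.loglik) < 1e-6 or lmm.extra["lambda"] > 0

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM
        df = _grouped_data(3)
        x_mat = sm.add_constant(df["x"].to_numpy())
        for method, reml in (("ML", False), ("REML", True)):
            own = iso.fit_random_intercept(df, "y", ["x"], "site", method=method)
            ref = MixedLM(df["y"].to_numpy(), x_mat, groups=df["site"]).fit(reml=reml)
            assert own.loglik == pytest.approx(ref.llf, abs=1e-6)
            assert own.coefficients["x"][0] == pytest.approx(ref.params[1], abs=1e-5)
            assert own.extra["sigma2_resid"] == pytest.approx(ref.scale, rel=1e-3)

    def test_ml_optimum_beats_variance_ratio_grid(self):
        df = _grouped_data(7)
        y = df["y"].to_numpy()
        x, _ = _design(df, ["x"])
        idx = [np.flatnonzero(df["site"].to_numpy() == g)
               for g in pd.unique(df["site"])]
        fit = iso.fit_random_intercept(df, "y", ["x"], "site", method="ML")
        grid = np.exp(np.linspace(-12, 8, 2000))
        best = max(_profiled_loglik(l, y, x, idx, reml=False)[0] for l in grid)
        assert fit.loglik >= best - 1e-8

    def test_variance_ratio_recovery_in_balanced_design(self):
        # true ratio sigma_group^2 / sigma_resid^2 = 1, 50 groups x 20
        ratios = []
        for rep in range(30):
            df = _grouped_data(100 + rep, n_groups=50, group_size=20,
                               group_sd=1.0, resid_sd=1.0)
            fit = iso.fit_random_intercept(df, "y", ["x"], "site", method="REML")
            ratios.append(fit.extra["sigma2_group"] / fit.extra["sigma2_resid"])
        assert abs(np.median(ratios) - 1.0) < 0.3

    def test_single_group_rejected(self):
        df = _grouped_data(1, n_groups=1, group_size=30)
        with pytest.raises(iso.DataError):
            iso.fit_random_intercept(df, "y", ["x"], "site")


class TestAICc:
    def test_direct_arithmetic(self):
        assert iso.aicc(0.0, 1, 100) == pytest.approx(2 + 4 / 98)

    def test_converges_to_aic_for_large_n(self):
        assert iso.aicc(-10.0, 3, 10 ** 7) == pytest.approx(20 + 6, rel=1e-6)

    def test_small_n_domain_error(self):
        with pytest.raises(ValueError):
            iso.aicc(-10.0, 5, 6)


def _triples_from_deltas(deltas, k=2, n=100):
    return [(f"m{i}", -d / 2.0, k, n) for i, d in enumerate(deltas)]


class TestSelectionTable:
    def test_published_delta_set_yields_seventy_percent_top_weight(self):
        table = iso.selection_table(_triples_from_deltas([0, 2.19, 5.19, 9.28, 12.15]))
        assert table["delta_aicc"].iloc[0] == 0.0
        assert round(float(table["weight"].iloc[0]), 2) == 0.70
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_models_split_evenly_and_single_model_gets_all(self):
        t2 = iso.selection_table([("a", -5.0, 2, 50), ("b", -5.0, 2, 50)])
        assert t2["weight"].tolist() == pytest.approx([0.5, 0.5])
        t1 = iso.selection_table([("only", -5.0, 2, 50)])
        assert t1["weight"].iloc[0] == pytest.approx(1.0)

    def test_support_and_averaging_flags(self):
        table = iso.selection_table(_triples_from_deltas([0, 1.9, 3.5, 6.0]))
        assert table["well_supported"].tolist() == [True, True, False, False]
        assert table["averaging_set"].tolist() == [True, True, True, False]

    def test_implausible_model_does_not_move_existing_weights(self):
        base = iso.selection_table(_triples_from_deltas([0, 2.0]))
        extended = iso.selection_table(_triples_from_deltas([0, 2.0, 50.0]))
        np.testing.assert_allclose(extended["weight"][:2], base["weight"],
                                   atol=1e-10)

    def test_constant_loglik_shift_leaves_deltas_and_weights(self):
        a = iso.selection_table([("x", -10.0, 2, 50), ("y", -12.0, 3, 50)])
        b = iso.selection_table([("x", -110.0, 2, 50), ("y", -112.0, 3, 50)])
        np.testing.assert_allclose(a["delta_aicc"], b["delta_aicc"])
        np.testing.assert_allclose(a["weight"], b["weight"])

    def test_mixed_sample_sizes_rejected(self):
        with pytest.raises(iso.ConfigurationError):
            iso.selection_table([("a", -5.0, 2, 50), ("b", -5.0, 2, 60)])


def _fit(name, loglik, coefs, k=2, n=50):
    return iso.ModelFit(name=name, response="y", terms=tuple(coefs),
                        has_random_intercept=False, loglik=loglik, k=k, n=n,
                        coefficients=coefs, r2_marginal=0.5)


class TestModelAverage:
    def test_shared_coefficient_passes_through_unchanged(self):
        fits = [_fit("a", np.log(3.0), {"X": (1.5, 0.2)}),
                _fit("b", 0.0, {"X": (1.5, 0.4)})]
        avg = iso.model_average(fits)
        row = avg[avg.predictor == "X"].iloc[0]
        assert row.estimate == pytest.approx(1.5)

    def test_natural_average_hand_case(self):
        # weights 0.75 / 0.25, coefficients 1.0 / 2.0 -> 1.25
        fits = [_fit("a", np.log(3.0), {"X": (1.0, 0.1)}),
                _fit("b", 0.0, {"X": (2.0, 0.1)})]
        avg = iso.model_average(fits)
        assert avg[avg.predictor == "X"].iloc[0].estimate == pytest.approx(1.25)

    def test_rvi_is_sum_of_weights_of_containing_models(self):
        # weights 0.6 / 0.3 / 0.1; X present in the first two -> RVI 0.9
        fits = [_fit("a", np.log(6.0), {"X": (1.0, 0.1), "Z": (0.5, 0.1)}),
                _fit("b", np.log(3.0), {"X": (1.0, 0.1)}),
                _fit("c", 0.0, {"Z": (0.2, 0.1)})]
        avg = iso.model_average(fits)
        assert avg[avg.predictor == "X"].iloc[0].rvi == pytest.approx(0.9)
        assert avg[avg.predictor == "Z"].iloc[0].rvi == pytest.approx(0.7)

    def test_buckland_variance_with_identical_estimates_has_no_spread_term(self):
        fits = [_fit("a", np.log(3.0), {"X": (1.5, 0.2)}),
                _fit("b", 0.0, {"X": (1.5, 0.2)})]
        avg = iso.model_average(fits)
        assert avg[avg.predictor == "X"].iloc[0].unconditional_se == pytest.approx(0.2)

    def test_full_convention_shrinks_toward_zero(self):
        fits = [_fit("a", np.log(3.0), {"X": (2.0, 0.1)}),
                _fit("b", 0.0, {"Z": (0.3, 0.1)})]
        nat = iso.model_average(fits, convention="natural")
        full = iso.model_average(fits, convention="full")
        x_nat = nat[nat.predictor == "X"].iloc[0].estimate
        x_full = full[full.predictor == "X"].iloc[0].estimate
        assert x_full == pytest.approx(0.75 * 2.0) and x_nat == pytest.approx(2.0)


def test_candidate_set_respects_marginality():
    for name, terms in iso.D15N_CANDIDATES:
        for t in terms:
            if ":" in t:
                a, b = t.split(":")
                assert a in terms and b in terms
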