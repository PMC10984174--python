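"""Gamma GLM, AICc bookkeeping, subset selection and model averaging."""

import numpy as np
import pandas as pd
import pytest

from roamkit import inference as inf


def _irls_oracle(y, X, tol=1e-12, maxiter=200):
    """Hand-rolled IRLS for a gamma GLM with log link.

    With the log link the gamma IRLS weights are identically 1, so each
    update is an OLS of the working response on the design — independent
    of the package's fitting route.
    """
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean())
    for _ in range(maxiter):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        new, *_ = np.linalg.lstsq(X, z, rcond=None)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def _fixture_20_rows():
    rng = np.random.default_rng(99)
    x1 = rng.uniform(0, 10, 20)
    x2 = rng.integers(0, 2, 20).astype(float)
    mu = np.exp(0.5 + 0.15 * x1 - 0.4 * x2)
    y = rng.gamma(3.0, mu / 3.0)
    return pd.Series(y), pd.DataFrame({"x1": x1, "x2": x2})


class TestGammaGlm:
    def test_constant_response_intercept_is_log_mean(self):
        y = pd.Series([5.0] * 10)
        fit = inf.fit_gamma_glm(y, pd.DataFrame(index=y.index))
        assert fit.params["Intercept"] == pytest.approx(np.log(5.0))
        assert fit.k == 2

    def test_matches_independent_irls(self):
        y, X = _fixture_20_rows()
        fit = inf.fit_gamma_glm(y, X)
        oracle = _irls_oracle(y, X)
        got = np.array([fit.params["Intercept"], fit.params["x1"],
                        fit.params["x2"]])
        np.testing.assert_allclose(got, oracle, atol=1e-6)

    def test_slope_recovery_within_3_se(self):
        hits = 0
        runs = 200
        for s in range(runs):
            rng = np.random.default_rng(s)
            x = rng.uniform(0, 400, 500)
            mu = np.exp(1.0 + 0.005 * x)
            y = rng.gamma(2.0, mu / 2.0)
            fit = inf.fit_gamma_glm(pd.Series(y), pd.DataFrame({"x": x}))
            ok_b0 = abs(fit.params["Intercept"] - 1.0) \
                <= 3 * fit.bse["Intercept"]
            ok_b1 = abs(fit.params["x"] - 0.005) <= 3 * fit.bse["x"]
            hits += ok_b0 and ok_b1
        assert hits / runs >= 0.99

    def test_nonpositive_response_rejected(self):
        y = pd.Series([1.0, -2.0, 3.0])
        with pytest.raises(ValueError, match="positive"):
            inf.fit_gamma_glm(y, pd.DataFrame(index=y.index))

    def test_ml_shape_score_equation(self):
        # at the ML shape the profile score must vanish
        y, X = _fixture_20_rows()
        fit = inf.fit_gamma_glm(y, X)
        from scipy import special
        mu = np.exp(
            fit.params["Intercept"]
            + X.to_numpy() @ fit.params[["x1", "x2"]].to_numpy())
        m = np.mean(np.log(y / mu) - y / mu)
        k = fit.shape
        assert np.log(k) - special.digamma(k) + 1 + m == \
            pytest.approx(0.0, abs=1e-8)


class TestAicc:
    def test_arithmetic(self):
        assert inf.aicc(0.0, 3, 29) == pytest.approx(6.0 + 24.0 / 25.0)

    def test_large_n_limit_is_aic(self):
        assert inf.aicc(-10.0, 3, 10**7) == pytest.approx(26.0, abs=1e-4)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            inf.aicc(0.0, 3, 4)

    def test_published_style_delta(self):
        # two candidate AICc values as printed in a model-selection table
        assert 182.7196 - 181.9789 == pytest.approx(0.7407)


def _covariate_table(rng, n=30, effect=0.0):
    t = pd.DataFrame({
        "sex": rng.choice(["M", "F"], n),
        "age": rng.uniform(2, 14, n),
        "neuroticism": rng.normal(0, 1, n),
        "road_density": rng.uniform(0, 300, n),
        "major_road": rng.integers(0, 2, n).astype(float),
        "start_ordinal_date": rng.uniform(120, 300, n),
    }, index=[f"c{i}" for i in range(n)])
    mu = np.exp(1.6 + effect * t["road_density"])
    t["area"] = rng.gamma(2.0, mu / 2.0)
    return t


class TestAllSubsets:
    def test_intrinsic_stage_has_8_candidates(self):
        rng = np.random.default_rng(0)
        t = _covariate_table(rng)
        ms = inf.all_subsets(t, t["area"], inf.INTRINSIC)
        assert len(ms.table) == 8
        assert ms.table["weight"].sum() == pytest.approx(1.0)
        assert ms.table["delta_aicc"].min() == 0.0

    def test_carried_predictor_in_every_candidate(self):
        rng = np.random.default_rng(1)
        t = _covariate_table(rng)
        ms = inf.all_subsets(t, t["area"], inf.EXTRINSIC, carried=("age",))
        assert all("age" in m for m in ms.table["model"])
        assert len(ms.table) == 8

    def test_null_competitive_under_pure_noise(self):
        hits = 0
        runs = 60
        for s in range(runs):
            rng = np.random.default_rng(10_000 + s)
            t = _covariate_table(rng, effect=0.0)
            ms = inf.all_subsets(t, t["area"], inf.INTRINSIC)
            null_delta = float(ms.table.loc[
                ms.table["model"].map(lambda m: m == ()),
                "delta_aicc"].iloc[0])
            hits += null_delta < 2.0
        assert hits / runs >= 0.90

    def test_animals_with_missing_covariates_dropped(self):
        rng = np.random.default_rng(2)
        t = _covariate_table(rng)
        t.loc[t.index[:5], "neuroticism"] = np.nan
        ms = inf.all_subsets(t, t["area"], inf.INTRINSIC)
        assert ms.best.n == 25

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        t = _covariate_table(rng)
        perm = t.sample(frac=1.0, random_state=1)
        a = inf.all_subsets(t, t["area"], inf.INTRINSIC)
        b = inf.all_subsets(perm, perm["area"], inf.INTRINSIC)
        for m in a.fits:
            pd.testing.assert_series_equal(a.fits[m].params,
                                           b.fits[m].params,
                                           atol=1e-9, rtol=0)

    def test_aicc_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(4)
        t = _covariate_table(rng, effect=0.005)
        a = inf.all_subsets(t, t["area"], inf.EXTRINSIC)
        t2 = t.copy()
        t2["road_density"] = t2["road_density"] / 1000.0  # metres -> km
        b = inf.all_subsets(t2, t2["area"], inf.EXTRINSIC)
        np.testing.assert_allclose(
            a.table.sort_values("model", key=lambda s: s.astype(str))
            ["AICc"].to_numpy(),
            b.table.sort_values("model", key=lambda s: s.astype(str))
            ["AICc"].to_numpy(), atol=1e-6)
        fa = a.fits[("road_density",)].params["road_density"]
        fb = b.fits[("road_density",)].params["road_density"]
        assert fb == pytest.approx(fa * 1000.0, rel=1e-5)


class TestRetention:
    def _model_set_with(self, effect):
        rng = np.random.default_rng(42)
        t = _covariate_table(rng, effect=effect)
        return inf.all_subsets(t, t["area"], inf.EXTRINSIC)

    def test_strong_effect_retained(self):
        ms = self._model_set_with(effect=0.008)
        kept = inf.retain_predictors(ms, inf.EXTRINSIC)
        assert "road_density" in kept

    def test_ci_overlapping_zero_blocks_retention(self):
        # age-style case: present in a top model but CI spans zero
        ms = self._model_set_with(effect=0.0)
        kept = inf.retain_predictors(ms, inf.EXTRINSIC, ci_level=0.9999)
        assert kept == ()

    def test_empty_top_set_empty_retention(self):
        ms = self._model_set_with(effect=0.0)
        # a cut so small only the best model (possibly the null) remains
        kept = inf.retain_predictors(ms, inf.EXTRINSIC, delta_cut=1e-9)
        best = ms.table.iloc[0]["model"]
        for p in inf.EXTRINSIC:
            if p not in best:
                assert p not in kept


class TestModelAverage:
    def test_single_model_returns_its_coefficients(self):
        rng = np.random.default_rng(7)
        t = _covariate_table(rng, effect=0.01)
        ms = inf.all_subsets(t, t["area"], ("road_density",))
        avg = inf.model_average(ms, delta_cut=1e-9)
        best = ms.best
        for c in best.params.index:
            assert avg.loc[c, "estimate"] == pytest.approx(
                float(best.params[c]))

    def test_absent_coefficient_halved_at_equal_weight(self):
        # two equal-weight models, coefficient present in only one:
        # full averaging gives c/2
        f1 = inf.FittedGlm(("x",), pd.Series({"Intercept": 1.0, "x": 0.8}),
                           pd.Series({"Intercept": 0.1, "x": 0.2}),
                           loglik=-10.0, shape=2.0, k=3, n=30,
                           columns={"x": ["x"]})
        f2 = inf.FittedGlm((), pd.Series({"Intercept": 1.1}),
                           pd.Series({"Intercept": 0.1}),
                           loglik=-11.0, shape=2.0, k=2, n=30, columns={})
        ms = inf.ModelSet(
            pd.DataFrame({
                "model": [("x",), ()], "df": [3, 2],
                "AICc": [100.0, 100.0], "delta_aicc": [0.0, 0.0],
                "weight": [0.5, 0.5]}),
            {("x",): f1, (): f2})
        avg = inf.model_average(ms, delta_cut=2.0)
        assert avg.loc["x", "estimate"] == pytest.approx(0.4)

    def test_equals_brute_force_weighted_sum(self):
        rng = np.random.default_rng(8)
        t = _covariate_table(rng, effect=0.006)
        ms = inf.all_subsets(t, t["area"], inf.EXTRINSIC)
        avg = inf.model_average(ms, delta_cut=2.0)
        top = ms.within(2.0)
        w = (top["weight"] / top["weight"].sum()).to_numpy()
        for c in avg.index:
            brute = sum(
                wi * float(ms.fits[m].params.get(c, 0.0))
                for wi, m in zip(w, top["model"]))
            assert avg.loc[c, "estimate"] == pytest.approx(brute, abs=1e-12)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(9)
        t = _covariate_table(rng, effect=0.006)
        ms = inf.all_subsets(t, t["area"], inf.EXTRINSIC)
        avg = inf.model_average(ms)
        assert (avg["ci_lower"] <= avg["estimate"]).all()
        assert (avg["estimate"] <= avg["ci_upper"]).all()


class TestTwoStage:
    def test_df_convention_matches_table_layout(self):
        # null model df 2 (intercept + shape); one-predictor models df 3
        rng = np.random.default_rng(10)
        t = _covariate_table(rng)
        ms = inf.all_subsets(t, t["area"], ("road_density",))
        df_by_model = dict(zip(ms.table["model"], ms.table["df"]))
        assert df_by_model[()] == 2
        assert df_by_model[("road_density",)] == 3

    def test_runs_end_to_end(self):
        rng = np.random.default_rng(11)
        t = _covariate_table(rng, effect=0.008)
        res = inf.run_two_stage(t, t["area"])
        assert len(res.intrinsic.table) == 8
        assert len(res.extrinsic.table) == 8
        assert "Intercept" in res.averaged.index
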