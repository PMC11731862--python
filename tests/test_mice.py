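import numpy as np
import pandas as pd
import pytest

from lookalike.design import design_matrix
from lookalike.errors import (
    DonorPoolError,
    ModelError,
    SchemaError,
    SeparationError,
    SingularDesignError,
)
from lookalike.mice import (
    ConditionalModelSpec,
    Phi,
    draw_parameters,
    fit_conditional,
    impute_from_conditional,
    run_mice,
)
from lookalike.schema import Schema, VariableSchema

from conftest import make_table


def _design(x):
    return pd.DataFrame({"Intercept": np.ones(len(x)), "x": np.asarray(x, dtype=float)})


class TestFitConditional:
    def test_exact_linear_fit_has_zero_residual_variance(self):
        x = np.arange(10.0)
        fit = fit_conditional(2 * x, _design(x), "bayes_linear")
        assert fit.params == pytest.approx([0.0, 2.0], abs=1e-10)
        assert fit.resid_var == 0.0

    def test_three_point_normal_equations_by_hand(self):
        # x=(0,1,2), y=(0,1,2): slope 1, intercept 0
        fit = fit_conditional([0.0, 1.0, 2.0], _design([0, 1, 2]), "bayes_linear")
        assert fit.params == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_single_class_logistic_is_separation_error(self):
        with pytest.raises(SeparationError):
            fit_conditional(np.ones(20), _design(np.arange(20)), "logistic")

    def test_rank_deficiency_names_collinear_columns(self):
        X = _design(np.arange(12.0))
        X["x2"] = 2 * X["x"]
        with pytest.raises(SingularDesignError) as err:
            fit_conditional(np.arange(12.0), X, "bayes_linear")
        assert {"x", "x2"} & set(err.value.columns)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ModelError, match="observed rows"):
            fit_conditional([1.0, 2.0], _design([0, 1]), "bayes_linear")

    def test_logistic_recovers_known_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = (rng.random(4000) < p).astype(float)
        fit = fit_conditional(y, _design(x), "logistic")
        assert fit.params == pytest.approx([0.5, 1.2], abs=0.2)

    def test_multinomial_tracks_observed_codes(self):
        rng = np.random.default_rng(1)
        y = rng.choice([0.0, 2.0], size=300)  # middle category unobserved
        fit = fit_conditional(y, _design(rng.normal(size=300)), "multinomial")
        assert fit.n_categories == 2
        assert list(fit.category_codes) == [0, 2]


class TestDrawParameters:
    def test_zero_residual_variance_is_degenerate_posterior(self):
        x = np.arange(10.0)
        fit = fit_conditional(2 * x, _design(x), "bayes_linear")
        phi = draw_parameters(fit, np.random.default_rng(0))
        assert phi.beta == pytest.approx(fit.params, abs=0.0)
        assert phi.sigma2 == 0.0

    def test_fixed_rng_state_reproduces_phi(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        x = np.random.default_rng(9).normal(size=50)
        y = x + np.random.default_rng(10).normal(size=50)
        fit = fit_conditional(y, _design(x), "bayes_linear")
        p1, p2 = draw_parameters(fit, rng1), draw_parameters(fit, rng2)
        assert np.array_equal(p1.beta, p2.beta)
        assert p1.sigma2 == p2.sigma2

    def test_draw_covariance_matches_posterior_within_15pct(self):
        # MC check of the sampling distribution over 2000 draws
        rng_data = np.random.default_rng(3)
        x = rng_data.uniform(1, 3, size=200)
        y = 1.0 + 0.5 * x + rng_data.normal(scale=1.0, size=200)
        fit = fit_conditional(y, _design(x), "bayes_linear")
        target = fit.resid_var * fit.xtx_inv
        rng = np.random.default_rng(12)
        draws = np.array([draw_parameters(fit, rng).beta for _ in range(2000)])
        emp = np.cov(draws.T)
        assert np.all(np.abs(emp - target) <= 0.15 * np.abs(target))

    def test_large_sample_normal_draw_centres_on_mle(self):
        rng_data = np.random.default_rng(4)
        x = rng_data.normal(size=2000)
        p = 1 / (1 + np.exp(-x))
        y = (rng_data.random(2000) < p).astype(float)
        fit = fit_conditional(y, _design(x), "logistic")
        rng = np.random.default_rng(6)
        draws = np.array([draw_parameters(fit, rng).beta for _ in range(1000)])
        assert draws.mean(axis=0) == pytest.approx(fit.params, abs=0.02)


class TestImputeFromConditional:
    def test_zero_missing_rows_gives_empty_output(self):
        phi = Phi(family="bayes_linear", beta=np.array([0.0, 1.0]), sigma2=1.0)
        out = impute_from_conditional(phi, _design([]), "bayes_linear", np.random.default_rng(0))
        assert out.size == 0

    def test_pmm_draws_live_in_observed_support(self):
        rng_data = np.random.default_rng(7)
        x = rng_data.normal(size=100)
        y = np.round(2 * x + rng_data.normal(size=100), 1)
        fit = fit_conditional(y, _design(x), "pmm")
        rng = np.random.default_rng(8)
        phi = draw_parameters(fit, rng)
        phi.pmm_k = 5
        out = impute_from_conditional(phi, _design(rng.normal(size=50)), "pmm", rng)
        assert set(out) <= set(y)

    def test_pmm_donor_pool_too_small(self):
        x = np.arange(5.0)
        fit = fit_conditional(x * 2, _design(x), "pmm")
        phi = draw_parameters(fit, np.random.default_rng(0))
        phi.pmm_k = 10
        with pytest.raises(DonorPoolError):
            impute_from_conditional(phi, _design([1.0]), "pmm", np.random.default_rng(0))

    def test_logistic_imputation_proportion(self):
        # Bernoulli mean oracle: beta = (logit 0.3, 0) -> share ~ 0.3
        logit03 = np.log(0.3 / 0.7)
        phi = Phi(family="logistic", beta=np.array([logit03, 0.0]))
        rng = np.random.default_rng(21)
        out = impute_from_conditional(phi, _design(rng.normal(size=10_000)), "logistic", rng)
        assert out.mean() == pytest.approx(0.3, abs=3 * np.sqrt(0.21 / 10_000))

    def test_gaussian_imputation_moments(self):
        phi = Phi(family="bayes_linear", beta=np.array([10.0, 0.0]), sigma2=4.0)
        rng = np.random.default_rng(22)
        out = impute_from_conditional(phi, _design(np.zeros(20_000)), "bayes_linear", rng)
        assert out.mean() == pytest.approx(10.0, abs=3 * 2 / np.sqrt(20_000))
        assert out.std() == pytest.approx(2.0, rel=0.05)


def _gaussian_mcar_table(n=400, frac=0.5, mean=10.0, sd=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.normal(mean, sd, size=n)
    observed = np.ones(n, dtype=bool)
    observed[rng.choice(n, size=int(n * frac), replace=False)] = False
    schema = Schema([VariableSchema("y", "continuous")])
    return make_table({"y": np.where(observed, y, np.nan)}, schema, {"y": observed.tolist()})


class TestRunMice:
    def test_complete_input_returns_m_identical_copies(self, tiny_schema):
        table = make_table(
            {"x": [1.0, 2.0, 3.0, 4.0], "g": list("abab"), "y": [1.0, 2.0, 3.0, 4.0]},
            tiny_schema,
        )
        spec = ConditionalModelSpec("y", "bayes_linear", ("x",))
        result = run_mice(table, [spec], m=3, T=2, seed=1)
        for df in result.datasets:
            pd.testing.assert_frame_equal(df, table.data)

    def test_observed_cells_preserved_exactly(self):
        table = _gaussian_mcar_table(seed=5)
        spec = ConditionalModelSpec("y", "bayes_linear", ())
        result = run_mice(table, [spec], m=4, T=3, seed=2)
        obs = table.mask["y"].to_numpy()
        for df in result.datasets:
            assert np.array_equal(
                df.loc[obs, "y"].to_numpy(), table.data.loc[obs, "y"].to_numpy()
            )

    def test_no_missing_cells_remain(self):
        table = _gaussian_mcar_table(seed=6)
        result = run_mice(table, [ConditionalModelSpec("y", "bayes_linear", ())], m=3, T=2, seed=3)
        for df in result.datasets:
            assert not df["y"].isna().any()

    def test_between_imputation_variability(self):
        table = _gaussian_mcar_table(seed=7)
        result = run_mice(table, [ConditionalModelSpec("y", "bayes_linear", ())], m=2, T=2, seed=4)
        mis = ~table.mask["y"].to_numpy()
        a, b = (df.loc[mis, "y"].to_numpy() for df in result.datasets)
        assert np.any(a != b)

    def test_seed_contract(self):
        table = _gaussian_mcar_table(seed=8)
        spec = [ConditionalModelSpec("y", "bayes_linear", ())]
        r1 = run_mice(table, spec, m=3, T=2, seed=99)
        r2 = run_mice(table, spec, m=3, T=2, seed=99)
        for d1, d2 in zip(r1.datasets, r2.datasets):
            pd.testing.assert_frame_equal(d1, d2)

    def test_mcar_gaussian_mean_recovery(self):
        # MCAR oracle: the generating distribution N(10, 4)
        table = _gaussian_mcar_table(n=400, seed=9)
        result = run_mice(
            table, [ConditionalModelSpec("y", "bayes_linear", ())], m=20, T=2, seed=10
        )
        mis = ~table.mask["y"].to_numpy()
        imputed_means = [df.loc[mis, "y"].mean() for df in result.datasets]
        # 3 MC SEs: sd * sqrt(1/n_obs + 1/(m * n_mis))
        tol = 3 * 2.0 * np.sqrt(1 / 200 + 1 / (20 * 200))
        assert np.mean(imputed_means) == pytest.approx(10.0, abs=tol)

    def test_single_variable_T_invariance(self):
        # with p = 1 incomplete variable the Gibbs visit schedule has no
        # cross-variable dependence: T = 1 and T = 10 share one sampling
        # distribution; compare mean imputed values over 30 seeds
        means = {T: [] for T in (1, 10)}
        table = _gaussian_mcar_table(n=200, seed=11)
        mis = ~table.mask["y"].to_numpy()
        for T in means:
            for seed in range(30):
                r = run_mice(
                    table, [ConditionalModelSpec("y", "bayes_linear", ())], m=1, T=T, seed=seed
                )
                means[T].append(r.datasets[0].loc[mis, "y"].mean())
        m1, m10 = np.mean(means[1]), np.mean(means[10])
        pooled_se = np.sqrt(np.var(means[1]) / 30 + np.var(means[10]) / 30)
        assert abs(m1 - m10) < 3 * pooled_se

    def test_missing_variable_without_spec_rejected(self):
        table = _gaussian_mcar_table(seed=12)
        with pytest.raises(ModelError, match="without a conditional spec"):
            run_mice(table, [], m=2, T=1, seed=0)

    def test_incompatible_family_rejected(self, tiny_schema):
        table = make_table(
            {"x": [1.0, 2.0], "g": ["a", None], "y": [0.0, 1.0]},
            tiny_schema,
            {"x": [True, True], "g": [True, False], "y": [True, True]},
        )
        with pytest.raises(ModelError, match="incompatible"):
            run_mice(table, [ConditionalModelSpec("g", "bayes_linear", ("x",))], m=1, T=1, seed=0)

    def test_self_prediction_rejected(self):
        with pytest.raises(ModelError):
            ConditionalModelSpec("y", "bayes_linear", ("y",))

    def test_chained_two_variables_complete(self, tiny_schema):
        rng = np.random.default_rng(13)
        n = 300
        x = rng.normal(size=n)
        g = np.where(rng.random(n) < 0.5, "a", "b")
        y = x + (g == "b") + rng.normal(size=n)
        x_obs = rng.random(n) > 0.3
        g_obs = rng.random(n) > 0.3
        table = make_table(
            {"x": np.where(x_obs, x, np.nan), "g": np.where(g_obs, g, None), "y": y},
            tiny_schema,
            {"x": x_obs.tolist(), "g": g_obs.tolist(), "y": [True] * n},
        )
        specs = [
            ConditionalModelSpec("x", "bayes_linear", ("g", "y")),
            ConditionalModelSpec("g", "logistic", ("x", "y")),
        ]
        result = run_mice(table, specs, m=2, T=3, seed=14)
        for df in result.datasets:
            assert not df.isna().any().any()
            assert set(df["g"]) <= {"a", "b"}

    def test_diagnostics_shape(self):
        table = _gaussian_mcar_table(seed=15)
        r = run_mice(table, [ConditionalModelSpec("y", "bayes_linear", ())], m=3, T=4, seed=16)
        assert len(r.diagnostics["y"]["mean"]) == 3
        assert all(len(chain) == 4 for chain in r.diagnostics["y"]["mean"])

    def test_imputedset_write(self, tmp_path):
        table = _gaussian_mcar_table(seed=17)
        r = run_mice(table, [ConditionalModelSpec("y", "bayes_linear", ())], m=2, T=1, seed=18)
        out = r.write(tmp_path / "imp")
        assert (out / "imputation_000.csv").exists()
        assert (out / "manifest.json").exists()
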