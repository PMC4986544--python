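"""NB fitting, AICc ranking, weights, averaging, and regional substitution."""

import numpy as np
import pandas as pd
import pytest

from treedensity.models import (
    NBFit,
    aicc,
    akaike_weights,
    average_models,
    confidence_set,
    dredge,
    fit_nb,
    fit_region_models,
)


def simulate_nb(rng, n, beta, theta, p_extra=0):
    p = len(beta) - 1 + p_extra
    X = rng.standard_normal((n, p))
    eta = beta[0] + X[:, : len(beta) - 1] @ np.asarray(beta[1:])
    mu = np.exp(eta)
    y = rng.negative_binomial(theta, theta / (theta + mu))
    return y, X


class TestFitNB:
    def test_intercept_only_fitted_mean_is_sample_mean(self, rng):
        y, _ = simulate_nb(rng, 500, [np.log(150)], theta=4)
        fit = fit_nb(y, np.ones((500, 1)))
        assert np.exp(fit.beta[0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_parameter_recovery_within_standard_errors(self, rng):
        beta, theta = [np.log(200), 0.5, -0.3], 4.0
        y, X = simulate_nb(rng, 5000, beta, theta)
        fit = fit_nb(y, np.column_stack([np.ones(5000), X]))
        se = np.sqrt(np.diag(fit.cov_beta))
        assert np.all(np.abs(fit.beta - beta) < 3 * se)
        assert abs(fit.theta - theta) / theta < 0.25

    def test_loglik_at_optimum_beats_truth(self, rng):
        from scipy import stats

        beta, theta = [np.log(100), 0.4], 5.0
        y, X = simulate_nb(rng, 1000, beta, theta)
        Xd = np.column_stack([np.ones(1000), X])
        fit = fit_nb(y, Xd)
        mu_true = np.exp(Xd @ np.asarray(beta))
        ll_true = stats.nbinom.logpmf(y, theta, theta / (theta + mu_true)).sum()
        assert fit.loglik >= ll_true - 1e-6

    def test_rank_deficient_design_rejected(self, rng):
        y, X = simulate_nb(rng, 100, [np.log(50), 0.2], theta=5)
        Xd = np.column_stack([np.ones(100), X, X])  # duplicated column
        with pytest.raises(ValueError, match="rank"):
            fit_nb(y, Xd)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_nb(np.array([-1.0, 2.0, 3.0, 4.0]), np.ones((4, 1)))


def make_fit(loglik, k_beta, n):
    return NBFit(terms=("const",) + tuple(f"x{i}" for i in range(k_beta - 1)),
                 beta=np.zeros(k_beta), cov_beta=np.eye(k_beta), theta=1.0,
                 loglik=loglik, n_obs=n, converged=True)


class TestAICc:
    def test_direct_formula_arithmetic(self):
        # k_params = 3 means 2 beta terms + dispersion
        fit = make_fit(-100.0, k_beta=2, n=50)
        assert aicc(fit) == pytest.approx(206 + 24 / 46)

    def test_converges_to_aic_for_large_n(self):
        fit_small = make_fit(-100.0, k_beta=2, n=50)
        fit_big = make_fit(-100.0, k_beta=2, n=10**7)
        aic = -2 * -100.0 + 2 * 3
        assert abs(aicc(fit_big) - aic) < 1e-5
        assert aicc(fit_small) > aic

    def test_penalty_monotone_in_k_at_equal_loglik(self):
        assert aicc(make_fit(-100.0, 2, 100)) < aicc(make_fit(-100.0, 3, 100))

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(make_fit(-10.0, k_beta=3, n=5))


class TestAkaikeWeights:
    def test_single_model(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_equal_aicc_symmetry(self):
        assert akaike_weights([10.0, 10.0]) == pytest.approx([0.5, 0.5])

    def test_delta_two_formula(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.73106, 0.26894], abs=1e-4)

    def test_weights_sum_to_one(self, rng):
        w = akaike_weights(rng.uniform(100, 200, size=20))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class FakeSet:
    def __init__(self, weights):
        self.weights = np.asarray(weights)
        self.fits = [make_fit(-10.0 - i, 2, 100) for i in range(len(weights))]


class TestConfidenceSet:
    @pytest.mark.parametrize("weights,expected", [
        ([0.97, 0.02, 0.01], 1),
        ([0.5, 0.3, 0.15, 0.05], 3),
        ([0.1] * 10, 10),
    ])
    def test_smallest_prefix_reaching_cum(self, weights, expected):
        fits, w = confidence_set(FakeSet(weights), cum=0.95)
        assert len(fits) == expected
        assert w.sum() == pytest.approx(1.0)


class TestAverageModels:
    def test_single_model_identity(self, rng):
        y, X = simulate_nb(rng, 300, [np.log(80), 0.3], theta=5)
        fit = fit_nb(y, np.column_stack([np.ones(300), X]), terms=("const", "x1"))
        avg = average_models([fit], np.array([1.0]))
        assert np.allclose(avg.beta, fit.beta)
        assert np.allclose(avg.cov, fit.cov_beta)
        assert avg.theta == pytest.approx(fit.theta)

    def test_identical_betas_have_zero_between_model_variance(self):
        f1 = make_fit(-10, 2, 100)
        f2 = make_fit(-11, 2, 100)
        f1.beta = f2.beta = np.array([1.0, 2.0])
        avg = average_models([f1, f2], np.array([0.6, 0.4]))
        assert np.allclose(avg.beta, [1.0, 2.0])
        assert np.allclose(avg.cov, np.eye(2))  # within-model only

    def test_absent_term_averages_with_zero(self):
        f1 = make_fit(-10, 2, 100)  # terms (const, x0)
        f1.beta = np.array([0.5, 2.0])
        f2 = make_fit(-11, 1, 100)  # intercept-only
        f2.beta = np.array([0.5])
        avg = average_models([f1, f2], np.array([0.6, 0.4]))
        assert avg.terms == ("const", "x0")
        assert avg.beta[1] == pytest.approx(0.6 * 2.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            average_models([], np.array([]))


class TestDredge:
    def test_no_terms_yields_single_model(self, rng):
        y, _ = simulate_nb(rng, 200, [np.log(60)], theta=4)
        mset = dredge(y, pd.DataFrame(index=range(200)))
        assert len(mset.fits) == 1
        assert mset.fits[0].terms == ("const",)

    def test_one_term_yields_two_models(self, rng):
        y, X = simulate_nb(rng, 200, [np.log(60), 0.4], theta=4)
        mset = dredge(y, pd.DataFrame({"x1": X[:, 0]}))
        assert len(mset.fits) == 2
        assert mset.delta[0] == 0.0
        assert mset.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_p_max_guard(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 13)), columns=[f"x{i}" for i in range(13)])
        with pytest.raises(ValueError, match="p_max"):
            dredge(np.ones(100), X)

    def test_strong_predictors_win(self, rng):
        y, X = simulate_nb(rng, 2000, [np.log(150), 0.5, -0.4], theta=5, p_extra=2)
        terms = pd.DataFrame(X, columns=["s1", "s2", "n1", "n2"])
        mset = dredge(y, terms)
        best = set(mset.fits[0].terms)
        assert {"s1", "s2"} <= best


class TestFitRegionModels:
    def test_below_threshold_biome_substituted_with_provenance(self, rng):
        y, X = simulate_nb(rng, 500, [np.log(100), 0.4], theta=5, p_extra=1)
        plots = pd.DataFrame({"trees_per_ha": y, "c1": X[:, 0], "c2": X[:, 1]})
        plots["biome_id"] = np.where(np.arange(500) < 451, 1, 2)  # biome 2: 49 plots
        models = fit_region_models(plots, ["c1", "c2"], min_n=50, substitutions={2: 1})
        assert models[1].provenance == "own"
        assert models[2].provenance == "substituted-from:1"
        assert np.allclose(models[2].beta, models[1].beta)
        assert models[2].n_obs == 49

    def test_exactly_min_n_gets_own_model(self, rng):
        y, X = simulate_nb(rng, 250, [np.log(100), 0.4], theta=5, p_extra=1)
        plots = pd.DataFrame({"trees_per_ha": y, "c1": X[:, 0], "c2": X[:, 1]})
        plots["biome_id"] = np.where(np.arange(250) < 200, 1, 2)  # biome 2: exactly 50
        models = fit_region_models(plots, ["c1", "c2"], min_n=50, substitutions={2: 1})
        assert models[2].provenance == "own"

    def test_data_poor_biome_without_analog_is_error(self, rng):
        y, X = simulate_nb(rng, 120, [np.log(100), 0.4], theta=5, p_extra=1)
        plots = pd.DataFrame({"trees_per_ha": y, "c1": X[:, 0], "c2": X[:, 1]})
        plots["biome_id"] = np.where(np.arange(120) < 100, 1, 2)
        with pytest.raises(ValueError, match="no fitted analog"):
            fit_region_models(plots, ["c1", "c2"], min_n=50, substitutions={})

    def test_ecoregion_inherits_biome_model(self, rng):
        y, X = simulate_nb(rng, 300, [np.log(100), 0.4], theta=5, p_extra=1)
        plots = pd.DataFrame({"trees_per_ha": y, "c1": X[:, 0], "c2": X[:, 1]})
        plots["biome_id"] = 1
        plots["ecoregion_id"] = np.where(np.arange(300) < 280, 10, 11)  # eco 11: 20 plots
        models = fit_region_models(plots, ["c1", "c2"], level="ecoregion", min_n=50)
        assert models[11].provenance == "substituted-from:biome:1"
        assert models[10].provenance == "own"
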