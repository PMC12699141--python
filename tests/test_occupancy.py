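"""Occupancy likelihood, maximum-likelihood fitting and prediction."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit
from sklearn.base import clone

import camocc as co
from camocc.occupancy import ModelSpec, OccupancyModel, _detection_stats

from conftest import enumeration_likelihood


class TestSiteLikelihood:
    def test_detected_history(self):
        assert co.site_likelihood([1, 0, 1], 0.5, [0.5] * 3) == pytest.approx(0.0625)

    def test_all_zero_history(self):
        assert co.site_likelihood([0, 0, 0], 0.5, [0.5] * 3) == pytest.approx(0.5625)

    def test_psi_one_reduces_to_bernoulli_product(self):
        p = [0.3, 0.6, 0.9]
        got = co.site_likelihood([1, 0, 1], 1.0, p)
        assert got == pytest.approx(0.3 * 0.4 * 0.9)

    def test_missing_occasions_drop_from_product(self):
        got = co.site_likelihood([1, np.nan, 1], 0.5, [0.5] * 3)
        assert got == pytest.approx(0.5 * 0.25)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            co.site_likelihood([1, 0], 0.5, [0.5, 0.5, 0.5])

    @given(
        data=st.data(),
        j=st.integers(1, 5),
    )
    def test_matches_latent_state_enumeration(self, data, j):
        history = data.draw(
            st.lists(st.sampled_from([0.0, 1.0, np.nan]), min_size=j, max_size=j)
        )
        if all(np.isnan(h) for h in history):
            history[0] = 0.0
        psi = data.draw(st.floats(0.0, 1.0))
        p = data.draw(st.lists(st.floats(0.0, 1.0), min_size=j, max_size=j))
        got = co.site_likelihood(history, psi, p)
        assert got == pytest.approx(enumeration_likelihood(history, psi, p), abs=1e-12)

    def test_total_probability_over_histories(self):
        rng = np.random.default_rng(11)
        for j in (1, 2, 3, 4):
            psi, p = rng.uniform(), rng.uniform(size=j)
            total = sum(
                co.site_likelihood(list(h), psi, p)
                for h in itertools.product([0.0, 1.0], repeat=j)
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestNegativeLogLikelihood:
    def test_single_site_intercepts_at_zero(self):
        spec = ModelSpec()
        data = np.array([[0.0, 0.0, 0.0]])
        nll = co.negative_log_likelihood([0.0, 0.0], spec, data)
        assert nll == pytest.approx(-np.log(0.5625))

    def test_additive_over_identical_sites(self):
        spec = ModelSpec()
        one = np.array([[1.0, 0.0, 1.0]])
        two = np.vstack([one, one])
        nll1 = co.negative_log_likelihood([0.3, -0.2], spec, one)
        nll2 = co.negative_log_likelihood([0.3, -0.2], spec, two)
        assert nll2 == pytest.approx(2 * nll1)

    def test_matches_enumeration_oracle_with_covariates(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 2, size=(5, 4)).astype(float)
        cov = pd.DataFrame({"x": rng.normal(size=5)})
        spec = ModelSpec(psi_terms=("x",), p_terms=("x",))
        theta = np.array([0.2, 0.5, -0.3, 0.4])
        psi = expit(theta[0] + theta[1] * cov["x"].to_numpy())
        p = expit(theta[2] + theta[3] * cov["x"].to_numpy())
        expected = -sum(
            np.log(enumeration_likelihood(data[i], psi[i], [p[i]] * 4))
            for i in range(5)
        )
        got = co.negative_log_likelihood(theta, spec, data, cov)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_wrong_parameter_count_raises(self):
        with pytest.raises(ValueError, match="parameters"):
            co.negative_log_likelihood([0.0], ModelSpec(), np.zeros((2, 3)))


class TestFit:
    def test_intercept_only_matches_grid_search(self, small_dataset):
        fit = co.fit_occupancy(ModelSpec(), small_dataset.matrix)
        d, m = _detection_stats(small_dataset.matrix.data)
        grid = np.arange(0.001, 1.0, 0.001)
        psi_g, p_g = np.meshgrid(grid, grid, indexing="ij")
        # NLL over the grid, aggregated through the (d, m) sufficient statistics
        pairs, counts = np.unique(np.stack([d, m], axis=1), axis=0,
                                  return_counts=True)
        nll = np.zeros_like(psi_g)
        for (dd, mm), c in zip(pairs, counts):
            lik = psi_g * p_g**dd * (1 - p_g) ** (mm - dd) + (1 - psi_g) * (dd == 0)
            nll -= c * np.log(lik)
        i, j = np.unravel_index(np.argmin(nll), nll.shape)
        assert expit(fit.beta[0]) == pytest.approx(grid[i], abs=2e-3)
        assert expit(fit.beta[1]) == pytest.approx(grid[j], abs=2e-3)
        assert fit.loglik >= -nll.min() - 1e-6

    def test_recovers_known_intercepts_at_large_n(self):
        design = co.SimulationDesign(
            n_sites=2000,
            n_occasions=15,
            covariates=("x",),
            corr=np.array([[1.0]]),
            beta_psi=(0.0,),
            beta_p=(0.0,),
            psi_intercept=logit(0.6),
            p_intercept=logit(0.3),
            seed=99,
        )
        ds = co.simulate(design)
        fit = co.fit_occupancy(ModelSpec(), ds.matrix)
        for k, truth in ((0, logit(0.6)), (1, logit(0.3))):
            assert abs(fit.beta[k] - truth) < 2 * fit.se[k]

    def test_saturated_detections_hit_boundary(self):
        data = np.ones((30, 6))
        fit = co.fit_occupancy(ModelSpec(), data)
        assert fit.boundary
        assert expit(fit.beta[0]) > 0.99

    def test_psi_boundary_gives_pooled_detection_rate(self):
        # every site detected at least once: psi-hat -> 1 and p-hat equals
        # the plain Bernoulli MLE (total detections / total occasions)
        rng = np.random.default_rng(4)
        data = rng.binomial(1, 0.5, size=(200, 15)).astype(float)
        data[data.sum(axis=1) == 0, 0] = 1.0
        fit = co.fit_occupancy(ModelSpec(), data)
        assert expit(fit.beta[0]) > 0.999
        assert expit(fit.beta[1]) == pytest.approx(data.mean(), abs=1e-3)

    def test_too_few_sites_raises(self):
        with pytest.raises(ValueError, match="sites"):
            co.fit_occupancy(ModelSpec(), np.zeros((3, 4)))

    def test_missing_covariate_raises(self, small_dataset):
        with pytest.raises(KeyError, match="nope"):
            co.fit_occupancy(
                ModelSpec(psi_terms=("nope",)),
                small_dataset.matrix,
                small_dataset.covariates,
            )


class TestPredict:
    def test_all_covariates_at_zero_gives_intercept(self, small_full_fit):
        pred = co.predict(small_full_fit, {}, "psi")
        assert pred.point == pytest.approx(expit(small_full_fit.beta[0]))
        assert pred.lower <= pred.point <= pred.upper

    def test_monotone_in_positive_coefficient(self, small_full_fit):
        beta = small_full_fit.coef("psi:forest_d")
        lo = co.predict(small_full_fit, {"forest_d": -1.0}, "psi").point
        hi = co.predict(small_full_fit, {"forest_d": 1.0}, "psi").point
        assert (hi > lo) == (beta > 0)

    def test_wald_interval_from_quadratic_form(self, small_full_fit):
        values = {"forest_d": 0.8, "d_streams": -0.5}
        pred = co.predict(small_full_fit, values, "psi")
        x = np.array([1.0, 0.8, -0.5])
        k = small_full_fit.n_psi
        eta = x @ small_full_fit.beta[:k]
        se = np.sqrt(x @ small_full_fit.vcov[:k, :k] @ x)
        z = 1.959963984540054
        assert pred.lower == pytest.approx(expit(eta - z * se), abs=1e-12)
        assert pred.upper == pytest.approx(expit(eta + z * se), abs=1e-12)

    def test_unknown_covariate_raises(self, small_full_fit):
        with pytest.raises(KeyError, match="unknown"):
            co.predict(small_full_fit, {"bogus": 1.0}, "psi")


class TestAicc:
    def test_worked_example(self):
        assert co.aicc(-100.0, 5, 40) == pytest.approx(200 + 10 + 60 / 34)

    def test_zero_parameters_is_minus_two_loglik(self):
        assert co.aicc(-50.0, 0, 10) == pytest.approx(100.0)

    def test_large_n_limit_is_plain_aic(self):
        assert co.aicc(-100.0, 5, 10**9) == pytest.approx(210.0, abs=1e-6)

    def test_small_n_undefined(self):
        with pytest.raises(ValueError):
            co.aicc(-100.0, 5, 6)


class TestModelSpecAndSerialization:
    def test_label_round_trip(self):
        spec = ModelSpec(psi_terms=("forest_d", "past"), p_terms=("crops",))
        assert spec.label == "p(crops)Ψ(forest_d+past)"
        assert ModelSpec.from_label(spec.label) == spec
        assert ModelSpec.from_label("p(.)Ψ(.)") == ModelSpec()

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelSpec(psi_terms=("a", "a"))

    def test_fit_result_json_round_trip(self, small_full_fit, tmp_path):
        path = tmp_path / "fit.json"
        small_full_fit.to_json(path)
        back = co.FitResult.from_json(path)
        assert back.spec == small_full_fit.spec
        np.testing.assert_allclose(back.beta, small_full_fit.beta)
        np.testing.assert_allclose(back.vcov, small_full_fit.vcov)
        assert back.aicc == pytest.approx(small_full_fit.aicc)


class TestEstimatorApi:
    def test_fit_sets_attributes_and_predicts(self, small_dataset):
        model = OccupancyModel(psi_terms=("forest_d",), p_terms=("past",))
        model.fit(small_dataset.covariates, small_dataset.matrix)
        assert model.converged_
        assert model.coef_.shape == (4,)
        psi = model.predict_psi(small_dataset.covariates)
        p = model.predict_p(small_dataset.covariates)
        np.testing.assert_allclose(
            model.predict(small_dataset.covariates), psi * p
        )
        assert np.all((psi > 0) & (psi < 1))

    def test_clone_and_get_params(self):
        model = OccupancyModel(psi_terms=("a",), gtol=1e-6)
        params = clone(model).get_params()
        assert params["psi_terms"] == ("a",)
        assert params["gtol"] == 1e-6

    def test_score_is_mean_site_loglik(self, small_dataset, intercept_fit):
        model = OccupancyModel().fit(None, small_dataset.matrix)
        expected = intercept_fit.loglik / small_dataset.matrix.n_sites
        assert model.score(None, small_dataset.matrix) == pytest.approx(expected)
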