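"""Model enumeration, AICc ranking, Akaike weights and model averaging."""

import numpy as np
import pandas as pd
import pytest

import camocc as co
from camocc.occupancy import FitResult, ModelSpec
from camocc.selection import read_model_table


def make_fit(aicc_value, beta=None, var=None, psi_terms=(), converged=True):
    """Hand-built FitResult for ranking/averaging arithmetic."""
    names = ["psi:(Intercept)"] + [f"psi:{t}" for t in psi_terms] + ["p:(Intercept)"]
    k = len(names)
    b = np.zeros(k)
    v = np.eye(k) * 0.01
    if beta is not None:
        for key, val in beta.items():
            b[names.index(key)] = val
    if var is not None:
        for key, val in var.items():
            i = names.index(key)
            v[i, i] = val
    return FitResult(
        spec=ModelSpec(psi_terms=psi_terms),
        names=names,
        beta=b,
        vcov=v,
        loglik=-aicc_value / 2,
        n_sites=100,
        aicc=aicc_value,
        converged=converged,
    )


class TestEnumeration:
    def test_six_by_six_candidates(self):
        specs = co.enumerate_models(list("abcdef"), list("uvwxyz"))
        assert len(specs) == 4096
        assert 3000 <= len(specs) <= 10000

    def test_double_intercept_only(self):
        specs = co.enumerate_models([], [])
        assert len(specs) == 1 and specs[0] == ModelSpec()

    def test_two_by_one(self):
        specs = co.enumerate_models(["a", "b"], ["u"])
        assert len(specs) == 8
        assert len(set(specs)) == 8

    def test_budget_guard_advises_cap(self):
        with pytest.raises(ValueError, match="max_terms"):
            co.enumerate_models(list("abcdefgh"), list("ijklmnop"), budget=20_000)

    def test_max_terms_cap(self):
        specs = co.enumerate_models(list("abcd"), [], max_terms=1)
        assert len(specs) == 5  # intercept-only + 4 singletons


class TestRankAndWeight:
    def test_two_model_weights(self):
        ms = co.rank_and_weight([make_fit(100.0), make_fit(102.0)])
        np.testing.assert_allclose(ms.delta, [0.0, 2.0])
        np.testing.assert_allclose(ms.weights, [0.7311, 0.2689], atol=5e-5)

    def test_equal_models_share_weight(self):
        ms = co.rank_and_weight([make_fit(50.0) for _ in range(4)])
        np.testing.assert_allclose(ms.weights, 0.25)

    def test_weights_sum_to_one_and_nothing_lost(self):
        rng = np.random.default_rng(0)
        fits = [make_fit(a) for a in rng.uniform(100, 130, size=17)]
        ms = co.rank_and_weight(fits)
        assert len(ms) == 17
        assert ms.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert sorted(f.aicc for f in fits) == [f.aicc for f in ms.results]

    def test_non_converged_excluded_with_warning(self):
        fits = [make_fit(100.0), make_fit(99.0, converged=False)]
        with pytest.warns(UserWarning, match="non-converged"):
            ms = co.rank_and_weight(fits)
        assert len(ms) == 1 and ms.n_excluded == 1
        with pytest.warns(UserWarning), pytest.raises(ValueError, match="converged"):
            co.rank_and_weight([make_fit(1.0, converged=False)])


class TestConfidenceSet:
    def test_strict_delta_threshold(self):
        ms = co.rank_and_weight(
            [make_fit(100.0), make_fit(101.98), make_fit(102.0), make_fit(104.0)]
        )
        conf = co.confidence_set(ms, 2.0)
        assert [f.aicc for f in conf.results] == [100.0, 101.98]
        assert conf.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert conf.renormalized

    def test_single_model_unchanged(self):
        ms = co.rank_and_weight([make_fit(10.0)])
        conf = co.confidence_set(ms)
        assert len(conf) == 1 and conf.weights[0] == pytest.approx(1.0)


class TestModelAverage:
    def test_equal_weight_mean(self):
        fits = [
            make_fit(100.0, beta={"psi:x": 0.2}, psi_terms=("x",)),
            make_fit(100.0, beta={"psi:x": 0.4}, psi_terms=("x",)),
        ]
        est = co.model_average(co.rank_and_weight(fits), "psi:x")
        assert est.estimate == pytest.approx(0.3)

    def test_shrinkage_toward_zero_when_term_absent(self):
        fits = [make_fit(100.0, beta={"psi:x": 0.5}, psi_terms=("x",)),
                make_fit(100.0)]
        ms = co.rank_and_weight(fits)
        w = ms.weights[[f.spec.psi_terms == ("x",) for f in ms.results].index(True)]
        est = co.model_average(ms, "psi:x")
        assert est.estimate == pytest.approx(w * 0.5)
        cond = co.model_average(ms, "psi:x", mode="conditional")
        assert cond.estimate == pytest.approx(0.5)

    def test_unconditional_se_hand_computed(self):
        fits = [
            make_fit(100.0, beta={"psi:x": 0.2}, var={"psi:x": 0.04},
                     psi_terms=("x",)),
            make_fit(101.0, beta={"psi:x": 0.6}, var={"psi:x": 0.09},
                     psi_terms=("x",)),
        ]
        ms = co.rank_and_weight(fits)
        w1, w2 = ms.weights
        est = w1 * 0.2 + w2 * 0.6
        se = w1 * np.sqrt(0.04 + (0.2 - est) ** 2) + w2 * np.sqrt(
            0.09 + (0.6 - est) ** 2
        )
        got = co.model_average(ms, "psi:x")
        assert got.estimate == pytest.approx(est, abs=1e-12)
        assert got.unconditional_se == pytest.approx(se, abs=1e-12)

    def test_single_member_reduces_to_model_estimate(self):
        fit = make_fit(100.0, beta={"psi:x": 0.37}, var={"psi:x": 0.02},
                       psi_terms=("x",))
        conf = co.confidence_set(co.rank_and_weight([fit]))
        est = co.model_average(conf, "psi:x")
        assert est.estimate == pytest.approx(0.37)
        assert est.unconditional_se == pytest.approx(np.sqrt(0.02))

    def test_missing_term_raises(self):
        ms = co.rank_and_weight([make_fit(100.0)])
        with pytest.raises(KeyError):
            co.model_average(ms, "psi:ghost")

    def test_order_invariance(self):
        fits = [
            make_fit(100.0, beta={"psi:x": 0.2}, psi_terms=("x",)),
            make_fit(100.5, beta={"psi:x": 0.7}, psi_terms=("x",)),
            make_fit(103.0),
        ]
        a = co.model_average(co.rank_and_weight(fits), "psi:x").estimate
        b = co.model_average(co.rank_and_weight(fits[::-1]), "psi:x").estimate
        assert a == pytest.approx(b, abs=1e-14)

    def test_dominant_model_drives_the_average(self):
        fits = [
            make_fit(100.0, beta={"psi:x": 0.5}, var={"psi:x": 0.04},
                     psi_terms=("x",)),
            make_fit(112.0, beta={"psi:x": 0.45}, var={"psi:x": 0.04},
                     psi_terms=("x",)),
        ]
        est = co.model_average(co.rank_and_weight(fits), "psi:x")
        assert abs(est.estimate - 0.5) < 0.01 * 0.2  # within 1% of the SE


class TestAveragedPredictions:
    def test_single_model_matches_predict(self, small_full_fit):
        ms = co.confidence_set(co.rank_and_weight([small_full_fit]))
        avg = co.average_predictions(ms, {"forest_d": 0.5}, "psi")
        direct = co.predict(small_full_fit, {"forest_d": 0.5}, "psi")
        assert avg.point == pytest.approx(direct.point, abs=1e-12)
        assert avg.lower == pytest.approx(direct.lower, abs=1e-9)
        assert avg.upper == pytest.approx(direct.upper, abs=1e-9)

    def test_average_lies_within_member_range(self, small_dataset):
        specs = co.enumerate_models(["forest_d"], ["past"])
        fits = co.fit_models(specs, small_dataset.matrix, small_dataset.covariates)
        conf = co.confidence_set(co.rank_and_weight(fits), threshold=10.0)
        avg = co.average_predictions(conf, {"forest_d": 1.0}, "psi")
        member_points = [
            co.predict(f, {"forest_d": 1.0}, "psi", strict=False).point
            for f in conf.results
        ]
        assert min(member_points) - 1e-12 <= avg.point <= max(member_points) + 1e-12

    def test_two_model_hand_computation(self):
        fits = [
            make_fit(100.0, beta={"psi:(Intercept)": 0.0}),
            make_fit(100.0, beta={"psi:(Intercept)": 1.0}),
        ]
        ms = co.rank_and_weight(fits)
        avg = co.average_predictions(ms, {}, "psi")
        from scipy.special import expit

        assert avg.point == pytest.approx(0.5 * expit(0.0) + 0.5 * expit(1.0))

    def test_unknown_covariate_rejected(self, small_full_fit):
        ms = co.rank_and_weight([small_full_fit])
        with pytest.raises(KeyError, match="unknown"):
            co.average_predictions(ms, {"ghost": 1.0}, "psi")


class TestModelTable:
    def test_csv_round_trip(self, small_dataset, tmp_path):
        specs = co.enumerate_models(["forest_d"], ["past"])
        fits = co.fit_models(specs, small_dataset.matrix, small_dataset.covariates)
        ms = co.rank_and_weight(fits)
        path = tmp_path / "table.csv"
        ms.to_csv(path)
        back = read_model_table(path)
        pd.testing.assert_frame_equal(back, ms.to_table())
        # labels parse back into specs
        for label in back["model"]:
            assert ModelSpec.from_label(label).label == label
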