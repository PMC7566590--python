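import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from odmodels import (
    FlowMatrix,
    NumericalError,
    ValidationError,
    bic,
    deviance,
    dice_coefficient,
    evaluate_model,
    fit_alpha,
    fit_beta,
    generate_system,
    gravity_predict,
    poisson_loglik,
    r_squared,
    refit_global_parameter,
    saturated_loglik,
)
from odmodels.inference import INCLUDE_ZEROS, compare_models, parse_fmin
from odmodels.synthetic import SyntheticConfig

from conftest import random_system


def loglik_loop(F, Fhat, f_min):
    """Naive per-pair oracle for the truncated Poisson log-likelihood."""
    total = 0.0
    n = F.n_sites
    for i in range(n):
        for j in range(n):
            if i == j or F.values[i, j] <= f_min:
                continue
            f, fh = float(F.values[i, j]), float(Fhat[i, j])
            total += -fh + f * math.log(fh) - math.lgamma(f + 1.0)
    return total


def deviance_loop(F, Fhat, f_min):
    total = 0.0
    n = F.n_sites
    for i in range(n):
        for j in range(n):
            if i == j or F.values[i, j] <= f_min:
                continue
            f, fh = float(F.values[i, j]), float(Fhat[i, j])
            term = (fh - f) + (f * math.log(f / fh) if f > 0 else 0.0)
            total += 2.0 * term
    return total


def single_pair(f_obs, f_hat):
    F = FlowMatrix(np.array([[0, f_obs], [0, 0]]))
    Fhat = np.array([[0.0, f_hat], [1.0, 0.0]])
    return F, Fhat


class TestPoissonLoglik:
    def test_zero_flow_unit_mean(self):
        F, Fhat = single_pair(0, 1.0)
        # only the (0,1) pair is nonzero-predicted... include both pairs:
        # contributions are -1 (F=0, Fhat=1) and -1 (F=0, Fhat=1)
        Fhat[1, 0] = 1.0
        assert poisson_loglik(F, Fhat, INCLUDE_ZEROS) == pytest.approx(-2.0)

    def test_hand_value_f2(self):
        F, Fhat = single_pair(2, 2.0)
        # -2 + 2 ln 2 - ln 2 on the included pair; the zero pair at f_min=0 drops
        assert poisson_loglik(F, Fhat, 0) == pytest.approx(-2.0 + math.log(2.0))

    def test_threshold_is_strict(self):
        F = FlowMatrix(np.array([[0, 0, 5], [0, 0, 0], [0, 0, 0]]))
        Fhat = np.full((3, 3), 2.0)
        # at f_min = 0 only the F = 5 pair contributes
        expect = -2.0 + 5.0 * math.log(2.0) - math.lgamma(6.0)
        assert poisson_loglik(F, Fhat, 0) == pytest.approx(expect)
        # at f_min = 5 nothing does
        assert poisson_loglik(F, Fhat, 5) == 0.0

    def test_include_zeros_sentinel_forms(self):
        F = FlowMatrix(np.array([[0, 3], [1, 0]]))
        Fhat = np.full((2, 2), 1.5)
        assert parse_fmin("include-zeros") == INCLUDE_ZEROS
        assert poisson_loglik(F, Fhat, "include-zeros") == pytest.approx(
            poisson_loglik(F, Fhat, -1)
        )

    def test_zero_prediction_rejected(self):
        F, Fhat = single_pair(1, 0.0)
        with pytest.raises(NumericalError):
            poisson_loglik(F, Fhat, 0)


class TestSaturatedLoglik:
    def test_zero_and_one_flows(self):
        F = FlowMatrix(np.array([[0, 1], [0, 0]]))
        assert saturated_loglik(F, INCLUDE_ZEROS) == pytest.approx(-1.0)

    def test_hand_value_f5(self):
        F = FlowMatrix(np.array([[0, 5], [0, 0]]))
        expect = -5.0 + 5.0 * math.log(5.0) - math.log(120.0)
        assert saturated_loglik(F, 0) == pytest.approx(expect)
        assert expect == pytest.approx(-1.74030, abs=1e-5)

    def test_upper_bounds_any_model(self):
        rng = np.random.default_rng(8)
        D, t, n, F = random_system(rng, 12)
        Fhat = gravity_predict(t, n, D, 1.0, "power")
        for f_min in (INCLUDE_ZEROS, 0, 3):
            assert saturated_loglik(F, f_min) >= poisson_loglik(F, Fhat, f_min)


class TestDeviance:
    def test_saturated_case_is_zero(self):
        F = FlowMatrix(np.array([[0, 4], [2, 0]]))
        assert deviance(F, F.values.astype(float) + np.eye(2), INCLUDE_ZEROS) == (
            pytest.approx(0.0)
        )

    def test_hand_value_zero_observation(self):
        F, Fhat = single_pair(0, 2.0)
        Fhat[1, 0] = 1e-12
        # restrict to the single (0,1) pair by choosing f_min = -1 on a
        # matrix whose other pair contributes ~2e-12
        assert deviance(F, Fhat, INCLUDE_ZEROS) == pytest.approx(4.0, abs=1e-9)

    @pytest.mark.parametrize("f_min", [INCLUDE_ZEROS, 0, 10, 100])
    def test_identity_with_saturated_likelihood(self, f_min):
        rng = np.random.default_rng(9)
        D, t, n, _ = random_system(rng, 20)
        Fhat = gravity_predict(t, n, D, 1.5, "power")
        F = FlowMatrix(np.random.default_rng(10).poisson(np.maximum(Fhat, 0.01)))
        d = deviance(F, Fhat, f_min)
        assert d >= 0
        assert d == pytest.approx(
            2.0 * (saturated_loglik(F, f_min) - poisson_loglik(F, Fhat, f_min)),
            rel=1e-9, abs=1e-9,
        )


class TestBic:
    def test_no_penalty_without_fitted_parameters(self):
        assert bic(-123.4, 0, 999) == pytest.approx(246.8)

    def test_closed_form(self):
        assert bic(-100.0, 1, 3109) == pytest.approx(math.log(3109) + 200.0)

    def test_empty_data_rejected(self):
        with pytest.raises(ValidationError):
            bic(-1.0, 1, 0)

    def test_ranking_consistency_with_loglik(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            l1, l2 = rng.normal(-1e4, 1e3, size=2)
            n = int(rng.integers(10, 10000))
            k = int(rng.integers(0, 2))
            assert np.sign(bic(l1, k, n) - bic(l2, k, n)) == np.sign(l2 - l1)


class TestLegacyMetrics:
    def test_dice(self):
        F = FlowMatrix(np.array([[0, 4], [0, 0]]))
        Fhat = np.full((2, 2), 2.0)
        assert dice_coefficient(F, Fhat) == pytest.approx(0.5)
        assert dice_coefficient(F, F.values.astype(float)) == 1.0
        assert dice_coefficient(F, np.zeros((2, 2))) == 0.0

    def test_dice_needs_flow(self):
        with pytest.raises(ValidationError):
            dice_coefficient(FlowMatrix(np.zeros((2, 2), int)), np.ones((2, 2)))

    def test_r_squared(self):
        F = FlowMatrix(np.array([[0, 0, 2], [4, 0, 0], [0, 0, 0]]))
        # observed off-diagonal values (0, 2, 4, 0, 0, 0), mean 1
        Fhat = F.values.astype(float)
        assert r_squared(F, Fhat) == pytest.approx(1.0)
        assert r_squared(F, np.full((3, 3), 1.0)) == pytest.approx(0.0)

    def test_r_squared_hand_value(self):
        F = FlowMatrix(np.array([[0, 0], [0, 0]]))
        with pytest.raises(ValidationError):
            r_squared(F, np.ones((2, 2)))
        F = FlowMatrix(np.array([[0, 2], [4, 0]]))
        Fhat = np.array([[0.0, 2.0], [3.0, 0.0]])
        # SS_res = 1, SS_tot = 2 -> 0.5
        assert r_squared(F, Fhat) == pytest.approx(0.5)


class TestFitAlpha:
    def test_proportional_data(self):
        Fhat0 = np.array([[0.0, 1.0, 2.0], [3.0, 0.0, 1.0], [2.0, 2.0, 0.0]])
        F = FlowMatrix((2 * Fhat0).astype(int))
        fit = fit_alpha(F, Fhat0)
        assert fit.param_value == pytest.approx(2.0)
        assert fit.param_se == pytest.approx(2.0 / math.sqrt(F.total))

    def test_closed_form_vs_numeric_optimum(self):
        rng = np.random.default_rng(12)
        Fhat0 = rng.uniform(0.5, 5.0, size=(8, 8))
        np.fill_diagonal(Fhat0, 0.0)
        F = FlowMatrix(rng.poisson(2.0 * Fhat0))
        fit = fit_alpha(F, Fhat0)
        res = minimize_scalar(
            lambda a: -poisson_loglik(F, a * Fhat0, INCLUDE_ZEROS),
            bounds=(1e-3, 50.0), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.param_value == pytest.approx(res.x, rel=1e-6)

    def test_optimality(self):
        rng = np.random.default_rng(13)
        Fhat0 = rng.uniform(0.5, 5.0, size=(6, 6))
        np.fill_diagonal(Fhat0, 0.0)
        F = FlowMatrix(rng.poisson(Fhat0))
        fit = fit_alpha(F, Fhat0)
        a = fit.param_value
        for factor in (0.99, 1.01):
            assert fit.loglik >= poisson_loglik(F, a * factor * Fhat0, INCLUDE_ZEROS)

    def test_degenerate_inputs_rejected(self):
        F = FlowMatrix(np.array([[0, 1], [0, 0]]))
        with pytest.raises(NumericalError):
            fit_alpha(F, np.zeros((2, 2)))
        with pytest.raises(NumericalError):
            fit_alpha(FlowMatrix(np.zeros((2, 2), int)), np.ones((2, 2)))


class TestFitBeta:
    def test_optimality_and_se(self, synth_system):
        s = synth_system
        fit = fit_beta(s.flows, s.sites, s.distances)
        b = fit.param_value
        for db in (-0.01, 0.01):
            fhat = gravity_predict(
                s.sites.out_flow.astype(float), s.sites.in_flow.astype(float),
                s.distances, b + db, "power",
            )
            assert fit.loglik >= poisson_loglik(s.flows, fhat, INCLUDE_ZEROS)
        assert fit.param_se is not None and fit.param_se > 0
        assert fit.warnings == []

    def test_distance_free_flows_flagged_at_boundary(self):
        # flows independent of distance: the MLE runs into the lower bound
        rng = np.random.default_rng(14)
        D, _, _, _ = random_system(rng, 30)
        t = np.full(30, 50000.0)
        n = np.full(30, 100.0)
        Fhat = gravity_predict(t, n, D, 0.0, "power")  # uniform over destinations
        F = FlowMatrix(rng.poisson(Fhat))
        from odmodels.data_model import SiteTable, derive_marginals

        O, I = derive_marginals(F)
        sites = SiteTable(
            site_id=np.array([f"s{i}" for i in range(30)], dtype=object),
            population=np.ones(30, dtype=int),
            out_flow=O, in_flow=I,
        )
        fit = fit_beta(F, sites, D)
        assert fit.param_value < 0.01
        assert any("bound" in w for w in fit.warnings)

    def test_exponential_deterrence_fit_on_km_distances(self, synth_system):
        # the exponential beta is an inverse length; on continental
        # kilometre scales the MLE sits at a few thousandths per km
        s = synth_system
        fit = fit_beta(s.flows, s.sites, s.distances, "exponential")
        assert fit.warnings == []
        assert 1e-4 < fit.param_value < 0.1
        assert fit.param_se is not None and fit.param_se > 0

    def test_truth_family_refit_recovers_beta(self):
        system = generate_system(SyntheticConfig(n_sites=200, seed=7))
        fit = refit_global_parameter(system.truth, system.distances, system.flows)
        assert fit.param_name == "beta"
        assert abs(fit.param_value - 2.0) <= 3.0 * fit.param_se

    def test_truth_family_refit_recovers_alpha(self):
        cfg = SyntheticConfig(
            n_sites=60, seed=21, truth_family="radiation",
            truth_variant="G", truth_alpha=1.6,
        )
        system = generate_system(cfg)
        fit = refit_global_parameter(system.truth, system.distances, system.flows)
        assert fit.param_name == "alpha"
        assert abs(fit.param_value - 1.6) <= 4.0 * fit.param_se


class TestVectorisedAgainstLoopOracle:
    def test_loglik_and_deviance_match_loop(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            nsites = int(rng.integers(5, 30))
            D, t, n, F = random_system(rng, nsites)
            Fhat = gravity_predict(t, n, D, 1.2, "power")
            for f_min in (INCLUDE_ZEROS, 0, 2):
                assert poisson_loglik(F, Fhat, f_min) == pytest.approx(
                    loglik_loop(F, Fhat, f_min), rel=1e-9
                )
                assert deviance(F, Fhat, f_min) == pytest.approx(
                    deviance_loop(F, Fhat, f_min), rel=1e-9
                )


class TestEvaluateAndCompare:
    def test_fit_result_invariants(self, synth_system):
        s = synth_system
        for name in ("gravity", "A", "C", "G"):
            r = evaluate_model(name, s.sites, s.distances, s.flows, 0)
            assert r.bic == pytest.approx(r.k * math.log(r.n_data) - 2 * r.loglik)
            assert r.deviance >= 0
            assert (r.k == 0) == (r.param_se is None)
            assert r.loglik_saturated >= r.loglik

    def test_bic_n_modes(self, synth_system):
        s = synth_system
        r_pairs = evaluate_model("B", s.sites, s.distances, s.flows, 0, "pairs")
        r_paper = evaluate_model("B", s.sites, s.distances, s.flows, 0, "paper")
        assert r_paper.n_data == s.sites.n_sites
        assert r_pairs.n_data == int((s.flows.values > 0).sum())
        assert r_pairs.loglik == r_paper.loglik

    def test_compare_isolates_model_failures(self, synth_system):
        s = synth_system
        results, errors = compare_models(
            ["gravity", "B", "nonsense"], s.sites, s.distances, s.flows
        )
        assert len(results) == 2
        assert len(errors) == 1 and errors[0]["model"] == "nonsense"
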