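"""Maximum-likelihood fitting, likelihood-ratio and Wald tests."""

import itertools

import numpy as np
import pytest

from mrdoc import (
    ModelSpec,
    expected_covariance,
    fit_ml,
    lrt,
    make_candidate_spec,
    mrdoc_spec,
    simulate_twin_study,
    recovery_scenario,
    theta_from_scenario,
    wald,
)
from mrdoc.identification import _random_point

from conftest import random_admissible_theta


def exact_groups(theta, n_mz=500, n_dz=500):
    return {
        "MZ": (expected_covariance(theta, "MZ"), n_mz),
        "DZ": (expected_covariance(theta, "DZ"), n_dz),
    }


class TestFitMl:
    def test_recovery_scenario2_recovery(self, recovery_thetas):
        """Exact data from the pleiotropic scenario: MR-DoC recovers the
        generating instrument, pleiotropy and causal paths."""
        theta = recovery_thetas[2]
        fit = fit_ml(exact_groups(theta, 1000, 1000), mrdoc_spec(re_zero=True))
        assert fit.converged
        assert fit.minus2ll == pytest.approx(0.0, abs=1e-6)
        assert fit.estimates.b1 == pytest.approx(0.3162, abs=1e-4)
        assert fit.estimates.b2 == pytest.approx(0.1599, abs=1e-4)
        assert fit.estimates.g1 == pytest.approx(theta.g1, abs=1e-5)
        assert np.abs(fit.estimates.to_array() - theta.to_array()).max() < 1e-4

    def test_null_scenario_no_false_causal_effect(self, recovery_thetas):
        """Pleiotropy without causation: the MR-DoC causal estimate is zero."""
        fit = fit_ml(exact_groups(recovery_thetas[3], 1000, 1000), mrdoc_spec(re_zero=True))
        assert abs(fit.estimates.g1) < 1e-6
        assert fit.estimates.b2 == pytest.approx(np.sqrt(0.10), abs=1e-4)

    @pytest.mark.parametrize("model_id", [2, 3, 4, 6])
    def test_identified_models_recover_random_points(self, model_id):
        """Every identified constraint pattern recovers its generating
        parameters from exact data, across random admissible points."""
        spec = make_candidate_spec(model_id)
        for k in range(5):
            theta = _random_point(spec, np.random.default_rng(100 * model_id + k))
            fit = fit_ml(exact_groups(theta), spec, compute_se=False)
            assert fit.converged
            dev = np.abs(fit.estimates.to_array() - theta.to_array()).max()
            assert dev < 1e-4, f"model {model_id}, point {k}: max deviation {dev}"

    def test_grid_search_oracle_two_free_parameters(self, recovery_thetas):
        """A 2-parameter fit (g1, b2 free, everything else at truth) lands on
        the same minimum as a dense grid search of the discrepancy."""
        theta = recovery_thetas[2]
        fixed = {n: getattr(theta, n) for n in
                 ("ra", "rc", "re", "a_x", "c_x", "e_x", "a_y", "c_y", "e_y",
                  "g2", "b1", "x")}
        spec = ModelSpec(fixed=fixed, label="toy2")
        # data generated at slightly different (g1, b2) so the optimum is interior
        gen = theta.replace(g1=0.15, b2=0.12)
        groups = exact_groups(gen, 200, 200)
        fit = fit_ml(groups, spec, compute_se=False)

        g1_grid = np.arange(0.10, 0.20, 1e-3)
        b2_grid = np.arange(0.07, 0.17, 1e-3)
        best = min(
            ((spec.full_theta([g, b]), g, b) for g, b in itertools.product(g1_grid, b2_grid)),
            key=lambda t: _discrepancy(t[0], groups),
        )
        assert fit.estimates.g1 == pytest.approx(best[1], abs=1e-3)
        assert fit.estimates.b2 == pytest.approx(best[2], abs=1e-3)

    def test_twin_order_invariance(self, recovery_thetas):
        """Swapping twin-1/twin-2 columns leaves the fit value unchanged."""
        from mrdoc import TwinDataset

        data = simulate_twin_study(recovery_thetas[2], 300, 300, mode="random", seed=5)
        perm = [3, 4, 5, 0, 1, 2]
        swapped = TwinDataset(mz=data.mz[:, perm], dz=data.dz[:, perm])
        f1 = fit_ml(data, mrdoc_spec(), compute_se=False)
        f2 = fit_ml(swapped, mrdoc_spec(), compute_se=False)
        assert f1.minus2ll == pytest.approx(f2.minus2ll, abs=1e-8)

    def test_saturated_style_fit_zero_misfit(self, rng):
        """A spec whose free parameters can reproduce the generating
        structure exactly scores a discrepancy of zero."""
        theta = random_admissible_theta(rng, re=0.0, g2=0.0)
        fit = fit_ml(exact_groups(theta), mrdoc_spec(re_zero=True), starts=theta)
        assert fit.minus2ll == pytest.approx(0.0, abs=1e-8)

    def test_refit_from_solution_is_stable(self, recovery_thetas):
        data = simulate_twin_study(recovery_thetas[1], 400, 400, mode="random", seed=9)
        fit = fit_ml(data, mrdoc_spec(re_zero=True), compute_se=False)
        refit = fit_ml(data, mrdoc_spec(re_zero=True), starts=fit.estimates,
                       compute_se=False)
        assert abs(refit.minus2ll - fit.minus2ll) < 1e-8

    def test_summary_and_raw_data_agree(self, recovery_thetas):
        data = simulate_twin_study(recovery_thetas[1], 300, 300, mode="random", seed=2)
        groups = {"MZ": (data.cov("MZ"), 300), "DZ": (data.cov("DZ"), 300)}
        f_raw = fit_ml(data, mrdoc_spec(re_zero=True), compute_se=False)
        f_sum = fit_ml(groups, mrdoc_spec(re_zero=True), compute_se=False)
        assert f_raw.minus2ll == pytest.approx(f_sum.minus2ll, abs=1e-8)


def _discrepancy(theta, groups):
    total = 0.0
    for zyg, (s, n) in groups.items():
        keep = [0, 1, 2, 4, 5] if zyg == "MZ" else list(range(6))
        sub = s[np.ix_(keep, keep)]
        sigma = expected_covariance(theta, zyg)[np.ix_(keep, keep)]
        sign, logdet = np.linalg.slogdet(sigma)
        _, logdet_s = np.linalg.slogdet(sub)
        total += n * (logdet + np.trace(np.linalg.solve(sigma, sub)) - logdet_s - len(keep))
    return total


class TestTests:
    def test_lrt_identical_fits(self, recovery_thetas):
        fit = fit_ml(exact_groups(recovery_thetas[1]), mrdoc_spec(re_zero=True),
                     starts=recovery_thetas[1], compute_se=False)
        delta, df, p = lrt(fit, fit)
        assert (delta, df, p) == (0.0, 0, 1.0)

    def test_lrt_true_null_zero_statistic(self, recovery_thetas):
        theta = recovery_thetas[1].replace(g1=0.0)
        full_spec = mrdoc_spec(re_zero=True)
        groups = exact_groups(theta, 1000, 1000)
        full = fit_ml(groups, full_spec, starts=theta, compute_se=False)
        null = fit_ml(groups, full_spec.constrain(g1=0.0), starts=theta,
                      compute_se=False)
        delta, df, p = lrt(full, null)
        assert delta == pytest.approx(0.0, abs=1e-6)
        assert df == 1

    def test_lrt_rejects_non_nested(self, recovery_thetas):
        groups = exact_groups(recovery_thetas[1])
        a = fit_ml(groups, mrdoc_spec(re_zero=True).constrain(b2=0.0), compute_se=False)
        b = fit_ml(groups, mrdoc_spec(re_zero=True).constrain(rc=0.0), compute_se=False)
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_wald_agrees_with_lrt_at_large_n(self, recovery_thetas):
        """Asymptotic equivalence of the two tests for g1 on random data."""
        theta = recovery_thetas[1]
        data = simulate_twin_study(theta, 4000, 4000, mode="random", seed=13)
        full_spec = mrdoc_spec(re_zero=True)
        full = fit_ml(data, full_spec, starts=theta)
        null = fit_ml(data, full_spec.constrain(g1=0.0),
                      starts=full.estimates.replace(g1=0.0), compute_se=False,
                      n_multistart=2)
        z, p_wald = wald(full, "g1")
        _, _, p_lrt = lrt(full, null)
        assert z**2 == pytest.approx(null.minus2ll - full.minus2ll, rel=0.2)

    def test_wald_guards(self, recovery_thetas):
        fit = fit_ml(exact_groups(recovery_thetas[1]), mrdoc_spec(re_zero=True),
                     starts=recovery_thetas[1])
        with pytest.raises(ValueError, match="fixed"):
            wald(fit, "re")
        fit_no_se = fit_ml(exact_groups(recovery_thetas[1]), mrdoc_spec(re_zero=True),
                           starts=recovery_thetas[1], compute_se=False)
        with pytest.raises(ValueError):
            wald(fit_no_se, "g1")
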