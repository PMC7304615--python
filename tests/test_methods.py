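"""Tests of the eight association procedures."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import rankdata, t as t_dist

from fsint.linmod import SampleData, fit_null, score_test
from fsint.methods import (
    FullStageConfig,
    METHODS,
    cauchy_combine,
    d_int,
    fs_int,
    i_int,
    mr_test,
    o_int,
    pts_int,
    run_method,
    ts_int,
    yjpt_test,
)
from fsint.simengine import SimulationScenario, generate_dataset


def _intercept_only(data: SampleData) -> SampleData:
    return SampleData(data.trait, np.ones((data.n, 1)), data.genotype)


def _outlier_data(n=600, seed=2024) -> SampleData:
    """Dataset with outlier-mixture errors; engineered to make the
    full-stage screen fire (the INT residuals stay covariate-correlated)."""
    rng = np.random.default_rng(seed)
    sc = SimulationScenario(
        n=n, gamma0=-2.0, gamma1=1.0, error_model="outlier_mixture", n_replicates=1, seed=0
    )
    return generate_dataset(sc, rng)


# ---------------------------------------------------------------- reductions


def test_pts_equals_ts_with_intercept_only(covariate_data):
    data = _intercept_only(covariate_data)
    assert pts_int(data).p_value == ts_int(data).p_value


def test_i_int_equals_ts_with_intercept_only(covariate_data):
    data = _intercept_only(covariate_data)
    assert i_int(data).p_value == pytest.approx(ts_int(data).p_value, rel=1e-12)


def test_fs_reduces_to_ts_bitwise_when_screen_passes(covariate_data):
    # normal errors: the INT residuals are uncorrelated with the covariates,
    # so the first screen passes and the full-stage test IS the two-stage test
    res_fs = fs_int(covariate_data)
    res_ts = ts_int(covariate_data)
    assert res_fs.iterations == 0
    assert res_fs.p_value == res_ts.p_value  # bitwise
    assert res_fs.statistic == res_ts.statistic


# ------------------------------------------------------- compositional oracles


def test_ts_int_matches_brute_force_composition(covariate_data):
    d = covariate_data
    # independent two-step path: lstsq residuals -> INT by hand -> score test
    coef, *_ = np.linalg.lstsq(d.covariates, d.trait, rcond=None)
    resid = d.trait - d.covariates @ coef
    r = ndtri((rankdata(resid) - 0.5) / d.n)
    expected = score_test(fit_null(r, d.covariates), d.genotype).p_value
    assert ts_int(d).p_value == pytest.approx(expected, rel=1e-12)


def test_pts_int_matches_brute_force_two_step(covariate_data):
    d = covariate_data
    coef, *_ = np.linalg.lstsq(d.covariates, d.trait, rcond=None)
    resid = d.trait - d.covariates @ coef
    r = ndtri((rankdata(resid) - 0.5) / d.n)
    # intercept-only score test written out directly
    rc = r - r.mean()
    gc = d.genotype - d.genotype.mean()
    u = float(d.genotype @ rc)
    v = float(rc @ rc) / (d.n - 1) * float(gc @ gc)
    from scipy.stats import chi2

    assert pts_int(d).p_value == pytest.approx(float(chi2.sf(u * u / v, 1)), rel=1e-10)


def test_d_int_invariant_to_monotone_trait_transform(covariate_data):
    d = covariate_data
    warped = dataclasses.replace(
        d, trait=np.exp(d.trait / 2.0) + d.trait**3 * 0.01
    )
    assert d_int(warped).p_value == pytest.approx(d_int(d).p_value, rel=1e-12)


def test_rank_based_methods_monotone_invariant_intercept_only(covariate_data):
    data = _intercept_only(covariate_data)
    warped = dataclasses.replace(data, trait=np.arctan(data.trait) * 3.0)
    for method in (d_int, i_int, ts_int, fs_int):
        assert method(warped).p_value == pytest.approx(
            method(data).p_value, rel=1e-12
        ), method.__name__


# ------------------------------------------------------------------- omnibus


def test_cauchy_combination_fixed_point():
    for p in (0.01, 0.2, 0.5, 0.9):
        assert cauchy_combine([p, p]) == pytest.approx(p, rel=1e-10)


def test_cauchy_combination_closed_form_oracle():
    p_d, p_i = 0.01, 0.5
    t = (math.tan((0.5 - p_d) * math.pi) + math.tan((0.5 - p_i) * math.pi)) / 2.0
    expected = 0.5 - math.atan(t) / math.pi
    assert cauchy_combine([p_d, p_i]) == pytest.approx(expected, rel=1e-12)


def test_o_int_combines_d_and_i(covariate_data):
    res = o_int(covariate_data)
    expected = cauchy_combine(
        [d_int(covariate_data).p_value, i_int(covariate_data).p_value]
    )
    assert res.p_value == pytest.approx(expected, rel=1e-12)


def test_o_int_falls_back_when_component_degenerate(covariate_data):
    mono = dataclasses.replace(covariate_data, genotype=np.zeros(covariate_data.n))
    res = o_int(mono)
    assert res.p_value == 1.0
    assert "degenerate_genotype" in res.flags


# ------------------------------------------------------------------ full-stage


def test_fs_int_step_trace_matches_independent_reimplementation():
    """Trace the iterative procedure with an independent statsmodels-based
    script and check the final p-value and iteration count agree."""
    import statsmodels.api as sm

    data = _outlier_data()
    x, y, g, n = data.covariates, data.trait, data.genotype, data.n

    def int_(v):
        return ndtri((rankdata(v) - 0.5) / len(v))

    r = int_(sm.OLS(y, x).fit().resid)
    iterations = 0
    fit = sm.OLS(r, x).fit()
    if np.any(fit.pvalues[1:] < 0.05):
        while True:
            alpha_tilde = fit.params
            r = int_(fit.resid)
            fit = sm.OLS(r, x).fit()
            iterations += 1
            if not np.any(fit.pvalues[1:] < 0.05):
                break
            if np.max(np.abs(alpha_tilde[1:] - fit.params[1:])) < 1e-6:
                break
            assert iterations < 100
    resid = fit.resid
    sigma2 = float(resid @ resid) / (n - x.shape[1])
    g_perp = g - x @ np.linalg.lstsq(x, g, rcond=None)[0]
    u = float(g @ resid)
    stat = u * u / (sigma2 * float(g_perp @ g_perp))
    from scipy.stats import chi2

    expected_p = float(chi2.sf(stat, 1))

    res = fs_int(data)
    assert res.iterations == iterations
    assert res.iterations >= 1  # the fixture must actually exercise the loop
    assert res.p_value == pytest.approx(expected_p, rel=1e-8)


def test_fs_int_self_consistency_after_screen_convergence():
    """When the loop stops via the screen, the final transformed residuals
    regressed on the covariates must show no screened p-value below 0.05."""
    from fsint.int_core import rank_inverse_normal

    exercised_loop = 0
    for seed in range(6):
        data = _outlier_data(seed=100 + seed)
        res = fs_int(data)
        assert res.converged
        exercised_loop += res.iterations > 0
        # replay the loop to recover the final residual state
        r = rank_inverse_normal(fit_null(data.trait, data.covariates).residuals)
        fit = fit_null(r, data.covariates)
        last_shift = np.inf
        for _ in range(res.iterations):
            prev = fit.coefficients
            r = rank_inverse_normal(fit.residuals)
            fit = fit_null(r, data.covariates)
            last_shift = float(np.max(np.abs(prev[1:] - fit.coefficients[1:])))
        pvals = fit.coefficient_pvalues()[1:]
        # a converged run stopped because the screen passed or the
        # coefficients stabilized
        assert np.all(pvals >= 0.05) or last_shift < 1e-6
    assert exercised_loop >= 1  # the fixtures must actually iterate sometimes


def test_fs_int_iteration_cap_and_flag():
    data = _outlier_data(seed=321)
    res = fs_int(data, FullStageConfig(max_iterations=1, coef_tolerance=1e-300))
    assert res.iterations <= 1
    if not res.converged:
        assert "max_iterations_reached" in res.flags


def test_fs_int_intercept_screen_toggle(covariate_data):
    res = fs_int(covariate_data, FullStageConfig(include_intercept_in_screen=True))
    assert 0.0 <= res.p_value <= 1.0


# ----------------------------------------------------------------- MR / YJPT


def test_mr_null_toy_not_significant():
    rng = np.random.default_rng(8)
    n = 200
    data = SampleData(
        trait=rng.normal(size=n),
        covariates=np.ones((n, 1)),
        genotype=rng.binomial(2, 0.4, n).astype(float),
    )
    assert mr_test(data).p_value > 0.05


def test_mr_recovers_effect_with_asymmetric_errors():
    rng = np.random.default_rng(9)
    n, beta = 4000, 0.5
    x1 = rng.normal(size=n)
    g = rng.binomial(2, 0.3, n).astype(float)
    # chi-squared errors: mean regression is biased toward the mean shift,
    # median regression still estimates beta consistently
    y = 0.4 * x1 + beta * g + rng.chisquare(2, n)
    data = SampleData(y, np.column_stack([np.ones(n), x1]), g)
    res = mr_test(data)
    assert res.beta_hat == pytest.approx(beta, abs=3 * res.se)


def test_mr_bootstrap_path_is_seeded_and_flagged():
    rng = np.random.default_rng(10)
    n = 150
    data = SampleData(
        trait=rng.normal(size=n),
        covariates=np.ones((n, 1)),
        genotype=rng.binomial(2, 0.3, n).astype(float),
    )
    a = mr_test(data, seed=3, bootstrap_reps=80, force_bootstrap=True)
    b = mr_test(data, seed=3, bootstrap_reps=80, force_bootstrap=True)
    assert "bootstrap_se" in a.flags
    assert a.p_value == b.p_value


def test_yjpt_identity_branch(covariate_data):
    from scipy.stats import yeojohnson

    y = covariate_data.trait
    assert np.allclose(yeojohnson(y, 1.0), y)


def test_yjpt_lambda_near_one_for_gaussian_data():
    rng = np.random.default_rng(12)
    n = 10_000
    x1 = rng.normal(size=n)
    g = rng.binomial(2, 0.3, n).astype(float)
    y = 1.0 + 0.5 * x1 + rng.normal(size=n)
    data = SampleData(y, np.column_stack([np.ones(n), x1]), g)
    res = yjpt_test(data)
    lam = float(next(f for f in res.flags if f.startswith("lambda=")).split("=")[1])
    assert abs(lam - 1.0) < 0.1


def test_yjpt_matches_r_car_oracle():
    """Frozen cross-check against R's car::powerTransform + lm on the same
    dataset (lambda 0.01123163, p 0.03561891, beta -0.1096782)."""
    rng = np.random.default_rng(404)
    sc = SimulationScenario(
        n=500, gamma0=-2, gamma1=1, error_model="chisq", n_replicates=1, seed=1
    )
    data = generate_dataset(sc, rng)
    res = yjpt_test(data)
    lam = float(next(f for f in res.flags if f.startswith("lambda=")).split("=")[1])
    assert lam == pytest.approx(0.01123163, abs=1e-4)
    assert res.p_value == pytest.approx(0.03561891, rel=1e-4)
    assert res.beta_hat == pytest.approx(-0.1096782, rel=1e-4)


# ------------------------------------------------------------------ registry


def test_registry_covers_all_methods_and_returns_valid_p(covariate_data):
    assert set(METHODS) == {
        "mr", "yjpt", "skat-score", "d-int", "i-int", "o-int", "ts-int", "fs-int",
    }
    for key in METHODS:
        res = run_method(key, covariate_data, seed=1)
        assert 0.0 <= res.p_value <= 1.0, key
        if key != "fs-int":
            assert res.iterations == 0, key


def test_skat_score_equals_plain_score_test(covariate_data):
    d = covariate_data
    expected = score_test(fit_null(d.trait, d.covariates), d.genotype)
    assert run_method("skat-score", d).p_value == expected.p_value


def test_unknown_method_rejected(covariate_data):
    with pytest.raises(KeyError):
        run_method("burden", covariate_data)
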