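"""The eight single-variant association procedures.

Five INT-based tests (partly/fully adjusted two-stage, direct, indirect,
omnibus, and the iterative full-stage procedure), the plain
covariate-adjusted score test (the single-variant equivalent of a
SKAT-type kernel test), median regression, and the Yeo-Johnson
power-transform regression.  Each maps a :class:`~fsint.linmod.SampleData`
to an :class:`~fsint.linmod.AssociationResult`.

The full-stage INT procedure (``fs_int``) is the centre of the package.
Starting from the INT of the covariate-only residuals, it checks whether
any covariate still predicts the transformed residuals (t-test screen at
0.05); while one does, it re-residualizes on the covariates and re-applies
the INT, stopping when the screen passes, when the covariate coefficients
stabilize to within 1e-6, or at an iteration cap.  The genotype is then
tested with the covariate-adjusted score test on the final transformed
residuals.  When the first screen already passes the procedure reduces
exactly to the fully adjusted two-stage INT test.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from fsint.int_core import RankNormalizeConfig, rank_inverse_normal
from fsint.linmod import (
    AssociationResult,
    SampleData,
    fit_null,
    score_test,
    wald_test,
)

__all__ = [
    "FullStageConfig",
    "METHODS",
    "run_method",
    "pts_int",
    "ts_int",
    "d_int",
    "i_int",
    "o_int",
    "fs_int",
    "mr_test",
    "yjpt_test",
    "cauchy_combine",
]

logger = logging.getLogger(__name__)

_INT = RankNormalizeConfig(offset=0.5)


@dataclass(frozen=True)
class FullStageConfig:
    """Tuning constants of the full-stage INT iteration.

    ``screen_alpha`` is the per-covariate significance screen applied to
    the transformed residuals (default 0.05); ``coef_tolerance`` is the
    L-infinity stabilization tolerance on the screened covariate
    coefficients (default 1e-6); ``max_iterations`` caps the loop.  The
    intercept is excluded from the screen by default: INT output is
    symmetric about zero, so the intercept of the re-fit is essentially
    zero by construction and its p-value carries no information.
    """

    screen_alpha: float = 0.05
    coef_tolerance: float = 1e-6
    max_iterations: int = 100
    include_intercept_in_screen: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.screen_alpha < 1.0:
            raise ValueError("screen_alpha must lie in (0, 1)")
        if self.coef_tolerance <= 0:
            raise ValueError("coef_tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


_FS_DEFAULT = FullStageConfig()


def _relabel(result: AssociationResult, method: str, **updates) -> AssociationResult:
    return dataclasses.replace(result, method=method, **updates)


def pts_int(data: SampleData) -> AssociationResult:
    """Partly adjusted two-stage INT test.

    INT of the covariate-only residuals, then a score test of the
    genotype with intercept-only adjustment (the covariates are *not*
    re-adjusted in the second stage).
    """
    null = fit_null(data.trait, data.covariates)
    r = rank_inverse_normal(null.residuals, _INT)
    intercept = np.ones((data.n, 1))
    res = score_test(fit_null(r, intercept), data.genotype)
    return _relabel(res, "pts-int")


def ts_int(data: SampleData) -> AssociationResult:
    """Fully adjusted two-stage INT test.

    INT of the covariate-only residuals, then a score test of the
    genotype re-adjusting the same covariates.
    """
    null = fit_null(data.trait, data.covariates)
    r = rank_inverse_normal(null.residuals, _INT)
    res = score_test(fit_null(r, data.covariates), data.genotype)
    return _relabel(res, "ts-int")


def d_int(data: SampleData) -> AssociationResult:
    """Direct INT test: INT of the trait itself, then a joint Wald test."""
    z = rank_inverse_normal(data.trait, _INT)
    res = wald_test(z, data.genotype, data.covariates)
    return _relabel(res, "d-int")


def i_int(data: SampleData) -> AssociationResult:
    """Indirect INT test.

    INT of the covariate-only residuals, tested against the
    covariate-residualized genotype without re-adjusting the covariates
    in the transformed-residual model.
    """
    null = fit_null(data.trait, data.covariates)
    r = rank_inverse_normal(null.residuals, _INT)
    g_res = null.project_out(data.genotype)
    intercept = np.ones((data.n, 1))
    res = score_test(fit_null(r, intercept), g_res)
    return _relabel(res, "i-int")


def cauchy_combine(p_values) -> float:
    """Cauchy (tangent-average) combination of p-values, equal weights.

    ``T = mean(tan((1/2 - p) pi))``; the combined p-value is the upper
    Cauchy tail of ``T``.  For very small p the summand is replaced by
    its asymptote ``1/(p pi)`` to avoid loss of precision.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError(f"p-values must lie in [0, 1]: {p}")
    small = p < 1e-16
    terms = np.empty_like(p)
    terms[small] = 1.0 / (p[small] * np.pi)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    t = float(np.mean(terms))
    return float(min(max(stats.cauchy.sf(t), 0.0), 1.0))


def o_int(data: SampleData) -> AssociationResult:
    """Omnibus INT test: Cauchy combination of the direct and indirect tests.

    If one sub-test is degenerate the other's p-value is used directly
    (flagged); if both are degenerate the result is degenerate.
    """
    res_d = d_int(data)
    res_i = i_int(data)
    deg_d = "degenerate_genotype" in res_d.flags
    deg_i = "degenerate_genotype" in res_i.flags
    if deg_d and deg_i:
        return AssociationResult(
            method="o-int", statistic=0.0, p_value=1.0, flags=("degenerate_genotype",)
        )
    if deg_d or deg_i:
        surviving = res_i if deg_d else res_d
        return _relabel(surviving, "o-int", flags=("one_component_degenerate",))
    p = cauchy_combine([res_d.p_value, res_i.p_value])
    statistic = float(np.mean([np.tan((0.5 - q) * np.pi) for q in (res_d.p_value, res_i.p_value)]))
    return AssociationResult(method="o-int", statistic=statistic, p_value=p)


def fs_int(data: SampleData, config: FullStageConfig = _FS_DEFAULT) -> AssociationResult:
    """Fully adjusted full-stage INT test (iterative re-normalization).

    Procedure: (1) residualize the trait on the covariates; (2) INT the
    residuals with offset 1/2; (3) regress the transformed residuals on
    the covariates and screen the covariate p-values at
    ``config.screen_alpha``; (4) while any screened p-value is below the
    screen, re-residualize on the covariates, re-apply the INT, and stop
    when the screen passes or the screened coefficients change by less
    than ``config.coef_tolerance`` (L-infinity); (5) score-test the
    genotype against the final transformed residuals, adjusting the
    covariates.  The returned result records the number of
    re-normalization iterations and whether a stopping criterion was met
    before ``config.max_iterations``.
    """
    x = data.covariates
    null_y = fit_null(data.trait, x)
    r = rank_inverse_normal(null_y.residuals, _INT)
    fit_r = fit_null(r, x)

    if config.include_intercept_in_screen:
        screened = np.arange(fit_r.p)
    else:
        screened = np.arange(1, fit_r.p)

    iterations = 0
    converged = True
    flags: tuple[str, ...] = ()
    needs_loop = screened.size > 0 and bool(
        np.any(fit_r.coefficient_pvalues()[screened] < config.screen_alpha)
    )
    while needs_loop:
        alpha_tilde = fit_r.coefficients
        r_star = rank_inverse_normal(fit_r.residuals, _INT)
        fit_star = fit_null(r_star, x)
        iterations += 1
        p_star = fit_star.coefficient_pvalues()
        coef_shift = float(
            np.max(np.abs(alpha_tilde[screened] - fit_star.coefficients[screened]))
        )
        fit_r = fit_star
        if not np.any(p_star[screened] < config.screen_alpha):
            break
        if coef_shift < config.coef_tolerance:
            break
        if iterations >= config.max_iterations:
            converged = False
            flags = ("max_iterations_reached",)
            logger.warning(
                "full-stage INT did not meet a stopping criterion within %d iterations",
                config.max_iterations,
            )
            break

    res = score_test(fit_r, data.genotype)
    return _relabel(
        res,
        "fs-int",
        iterations=iterations,
        converged=converged,
        flags=res.flags + flags,
    )


def mr_test(
    data: SampleData,
    seed: int | None = None,
    bootstrap_reps: int = 1000,
    force_bootstrap: bool = False,
) -> AssociationResult:
    """Median (0.5-quantile) regression test of the genotype coefficient.

    The trait is regressed on covariates plus genotype at the median;
    the default standard errors are the iid kernel-based errors of the
    quantile-regression fit.  When the default fit fails or yields a
    non-finite standard error (sparse designs, very rare variants), a
    case-resampling bootstrap of the coefficient is used instead and the
    result is flagged ``"bootstrap_se"``.
    """
    from statsmodels.regression.quantile_regression import QuantReg

    g = np.asarray(data.genotype, dtype=float)
    if np.ptp(g) == 0.0:
        return AssociationResult(
            method="mr", statistic=0.0, p_value=1.0, flags=("degenerate_genotype",)
        )
    design = np.column_stack([data.covariates, g])
    beta = se = None
    if not force_bootstrap:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = QuantReg(data.trait, design).fit(q=0.5)
            beta = float(fit.params[-1])
            se = float(fit.bse[-1])
            if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
                beta = se = None
        except Exception:  # singular / non-converged sparse fits
            beta = se = None
    if beta is not None and se is not None:
        t = beta / se
        df = data.n - design.shape[1]
        p = float(2.0 * stats.t.sf(abs(t), df))
        return AssociationResult(
            method="mr", statistic=t * t, p_value=p, beta_hat=beta, se=se
        )

    # bootstrap fallback
    rng = np.random.default_rng(seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = QuantReg(data.trait, design).fit(q=0.5, max_iter=200)
        beta = float(fit.params[-1])
    except Exception:
        return AssociationResult(
            method="mr", statistic=0.0, p_value=1.0, flags=("fit_failed",)
        )
    draws = np.empty(bootstrap_reps)
    n = data.n
    n_failed = 0
    for b in range(bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        gb = g[idx]
        if np.ptp(gb) == 0.0:
            draws[b] = np.nan
            n_failed += 1
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fb = QuantReg(data.trait[idx], design[idx]).fit(q=0.5, max_iter=200)
            draws[b] = fb.params[-1]
        except Exception:
            draws[b] = np.nan
            n_failed += 1
    good = draws[np.isfinite(draws)]
    if good.size < max(10, bootstrap_reps // 2):
        return AssociationResult(
            method="mr", statistic=0.0, p_value=1.0, flags=("bootstrap_failed",)
        )
    se = float(np.std(good, ddof=1))
    if se <= 0:
        return AssociationResult(
            method="mr", statistic=0.0, p_value=1.0, flags=("bootstrap_degenerate",)
        )
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult(
        method="mr", statistic=z * z, p_value=p, beta_hat=beta, se=se,
        flags=("bootstrap_se",),
    )


def _yeojohnson_loglik(lmbda: float, y: np.ndarray, q: np.ndarray) -> float:
    """Profile log-likelihood of the Yeo-Johnson parameter.

    Given the thin-Q factor of the regression design, the profile
    log-likelihood at ``lmbda`` is ``-n/2 log(SSE/n)`` plus the Jacobian
    term ``(lmbda - 1) * sum(sign(y) log(|y| + 1))``.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        z = stats.yeojohnson(y, lmbda)
    if not np.all(np.isfinite(z)):
        return -np.inf
    resid = z - q @ (q.T @ z)
    rss = float(resid @ resid)
    n = y.shape[0]
    if rss <= 0:
        return -np.inf
    jac = float(np.sum(np.sign(y) * np.log1p(np.abs(y))))
    return -0.5 * n * np.log(rss / n) + (lmbda - 1.0) * jac


def yjpt_test(
    data: SampleData,
    lambda_bounds: tuple[float, float] = (-5.0, 5.0),
    lambda_model: str = "full",
) -> AssociationResult:
    """Yeo-Johnson power-transform regression test.

    The transform parameter ``lambda`` is estimated by profile maximum
    likelihood under the joint model (covariates plus genotype by
    default; ``lambda_model="null"`` estimates it under the
    covariate-only model), then the genotype coefficient is Wald-tested
    on the transformed scale.
    """
    if lambda_model not in ("full", "null"):
        raise ValueError("lambda_model must be 'full' or 'null'")
    g = np.asarray(data.genotype, dtype=float)
    if np.ptp(g) == 0.0:
        return AssociationResult(
            method="yjpt", statistic=0.0, p_value=1.0, flags=("degenerate_genotype",)
        )
    if lambda_model == "full":
        design = np.column_stack([data.covariates, g])
    else:
        design = data.covariates
    q, _ = np.linalg.qr(design)
    y = data.trait
    opt = optimize.minimize_scalar(
        lambda lm: -_yeojohnson_loglik(lm, y, q),
        bounds=lambda_bounds,
        method="bounded",
        options={"xatol": 1e-5},
    )
    lam = float(opt.x)
    if not np.isfinite(opt.fun):
        raise ValueError("Yeo-Johnson profile likelihood is non-finite over the bounds")
    z = stats.yeojohnson(y, lam)
    res = wald_test(z, g, data.covariates)
    return _relabel(res, "yjpt", flags=res.flags + (f"lambda={lam:.4f}",))


#: string-keyed registry of all eight procedures
METHODS = {
    "mr": mr_test,
    "yjpt": yjpt_test,
    "skat-score": lambda data: _relabel(
        score_test(fit_null(data.trait, data.covariates), data.genotype), "skat-score"
    ),
    "d-int": d_int,
    "i-int": i_int,
    "o-int": o_int,
    "ts-int": ts_int,
    "fs-int": fs_int,
}


def run_method(key: str, data: SampleData, seed: int | None = None) -> AssociationResult:
    """Run the procedure registered under ``key`` on ``data``.

    ``seed`` feeds the stochastic parts of a method (currently only the
    median-regression bootstrap); deterministic methods ignore it.
    """
    if key not in METHODS:
        raise KeyError(f"unknown method {key!r}; choose from {sorted(METHODS)}")
    if key == "mr":
        return mr_test(data, seed=seed)
    return METHODS[key](data)
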