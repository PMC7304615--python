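"""Least-squares primitives and single-variant test statistics.

Everything in this module is written against a QR factorization of the
design matrix (no explicit normal-equation inverse), which keeps the
statistics stable for the ill-conditioned designs that show up when a
variant is nearly monomorphic.

Three tests of ``H0: beta = 0`` in the model ``y = X a + g b + e``:

* :func:`score_test` — ``U = g' e_hat``, ``V = sigma2 * g'(I-H)g``, with
  ``e_hat`` and ``sigma2`` from the covariate-only null fit; ``U^2/V`` is
  referred to chi-squared with 1 df.  For a single variant this is the
  same p-value a kernel (SKAT-type) test produces, whatever the variant
  weight.
* :func:`wald_test` — OLS of ``y`` on ``[X, g]``; ``t = b_hat/se`` with a
  finite-sample t reference on ``n - p - 1`` df.
* :func:`partial_f_test` — the nested-model F statistic; identical
  p-value to the Wald test (``t^2 = F``) and kept as an independent
  route for cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SampleData",
    "NullModelFit",
    "AssociationResult",
    "fit_null",
    "score_test",
    "wald_test",
    "partial_f_test",
    "RankDeficientError",
]

#: relative threshold below which a diagonal element of R flags collinearity
_RANK_TOL = 1e-10
#: condition-number threshold above which a warning is emitted
_COND_WARN = 1e8


class RankDeficientError(ValueError):
    """Raised when a design matrix is (numerically) rank deficient."""


@dataclass
class SampleData:
    """One variant's worth of analysis-ready data.

    ``trait`` (y, length n), ``covariates`` (X, n x p with a leading
    all-ones intercept column) and ``genotype`` (g, additive dosage in
    [0, 2]) — all complete cases, shared length.
    """

    trait: np.ndarray
    covariates: np.ndarray
    genotype: np.ndarray

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.genotype = np.asarray(self.genotype, dtype=float)
        n = self.trait.shape[0]
        if self.covariates.ndim != 2 or self.covariates.shape[0] != n:
            raise ValueError("covariates must be an n x p matrix matching the trait")
        if self.genotype.shape != (n,):
            raise ValueError("genotype must be a length-n vector matching the trait")
        if not np.all(np.isfinite(self.trait)):
            raise ValueError("trait contains non-finite values")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates contain non-finite values")
        if not np.all(np.isfinite(self.genotype)):
            raise ValueError("genotype contains non-finite values")
        if np.nanmin(self.genotype) < 0 or np.nanmax(self.genotype) > 2:
            raise ValueError("genotype dosages must lie in [0, 2]")
        if not np.allclose(self.covariates[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept (all ones)")

    @property
    def n(self) -> int:
        return self.trait.shape[0]


@dataclass
class NullModelFit:
    """Covariate-only OLS fit: coefficients, residuals and projection cache.

    ``q`` is the thin-Q factor of the design; products with the hat
    matrix ``H = Q Q'`` are formed as ``Q (Q' v)``.
    """

    coefficients: np.ndarray
    residuals: np.ndarray
    residual_variance: float
    design: np.ndarray = field(repr=False)
    q: np.ndarray = field(repr=False)
    r: np.ndarray = field(repr=False)
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.residuals.shape[0]

    @property
    def p(self) -> int:
        return self.design.shape[1]

    def project_out(self, v: np.ndarray) -> np.ndarray:
        """Return the component of ``v`` orthogonal to the design columns."""
        return v - self.q @ (self.q.T @ v)

    def coefficient_pvalues(self) -> np.ndarray:
        """Two-sided t-test p-values for each design coefficient."""
        # se_j = sigma * ||row j of R^{-1}||; solve rather than invert
        rinv = np.linalg.solve(self.r, np.eye(self.p))
        se = np.sqrt(self.residual_variance * np.sum(rinv * rinv, axis=1))
        df = self.n - self.p
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, self.coefficients / np.where(se > 0, se, 1.0), np.inf)
        return 2.0 * stats.t.sf(np.abs(t), df)


@dataclass
class AssociationResult:
    """Outcome of one association test on one variant."""

    method: str
    statistic: float
    p_value: float
    beta_hat: float | None = None
    se: float | None = None
    iterations: int = 0
    converged: bool = True
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def _qr_full_rank(x: np.ndarray, what: str = "design") -> tuple[np.ndarray, np.ndarray]:
    """Thin QR of ``x`` with a loud failure on rank deficiency."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    if scale == 0.0 or np.any(diag < _RANK_TOL * scale):
        bad = [int(j) for j in np.nonzero(diag < _RANK_TOL * max(scale, 1.0))[0]]
        raise RankDeficientError(
            f"{what} matrix is rank deficient (collinear columns {bad})"
        )
    if scale / diag.min() > _COND_WARN:
        warnings.warn(
            f"{what} matrix is ill-conditioned (condition ~{scale / diag.min():.2e})",
            RuntimeWarning,
            stacklevel=3,
        )
    return q, r


def fit_null(trait, covariates) -> NullModelFit:
    """Ordinary least squares of the trait on the covariates alone.

    Residual variance uses the unbiased denominator ``n - p``.  A perfect
    fit (zero residual sum of squares) is flagged ``degenerate``.
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(covariates, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need n > p; got n={n}, p={p}")
    q, r = _qr_full_rank(x, "covariate")
    qty = q.T @ y
    coef = np.linalg.solve(r, qty)
    resid = y - q @ qty
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    degenerate = sigma2 <= np.finfo(float).eps * max(1.0, float(y @ y))
    return NullModelFit(
        coefficients=coef,
        residuals=resid,
        residual_variance=sigma2,
        design=x,
        q=q,
        r=r,
        degenerate=degenerate,
    )


def score_test(null_fit: NullModelFit, genotype, covariates=None) -> AssociationResult:
    """Covariate-adjusted score test of a single variant.

    ``U = g' e_hat`` and ``V = sigma2 * g'(I - H) g`` with ``H`` the hat
    matrix of the null design; ``U^2 / V`` is referred to chi-squared
    with 1 df.  A genotype that is monomorphic, or fully explained by the
    covariates, carries no information: the result has ``p_value = 1``
    and the ``"degenerate_genotype"`` flag, so simulation denominators
    stay fixed.
    """
    g = np.asarray(genotype, dtype=float)
    if covariates is not None:
        x = np.asarray(covariates, dtype=float)
        if x.shape != null_fit.design.shape or not np.array_equal(x, null_fit.design):
            raise ValueError("covariates do not match the null-model design")
    g_perp = null_fit.project_out(g)
    gig = float(g_perp @ g_perp)
    scale = max(float(g @ g), 1.0)
    if gig <= 1e-12 * scale:
        return AssociationResult(
            method="score", statistic=0.0, p_value=1.0, flags=("degenerate_genotype",)
        )
    if null_fit.degenerate:
        return AssociationResult(
            method="score", statistic=0.0, p_value=1.0, flags=("degenerate_null_fit",)
        )
    u = float(g @ null_fit.residuals)
    v = null_fit.residual_variance * gig
    statistic = u * u / v
    p = float(stats.chi2.sf(statistic, 1))
    # beta_hat here is the score-based effect estimate U / (g'(I-H)g)
    return AssociationResult(
        method="score",
        statistic=statistic,
        p_value=p,
        beta_hat=u / gig,
        se=float(np.sqrt(v) / gig),
    )


def _joint_fit(trait, genotype, covariates):
    """OLS of the trait on ``[X, g]``; returns pieces shared by Wald and F."""
    y = np.asarray(trait, dtype=float)
    x = np.asarray(covariates, dtype=float)
    g = np.asarray(genotype, dtype=float)
    design = np.column_stack([x, g])
    n, k = design.shape
    if n <= k:
        raise ValueError(f"need n > p + 1; got n={n}, columns={k}")
    q, r = _qr_full_rank(design, "joint")
    qty = q.T @ y
    coef = np.linalg.solve(r, qty)
    resid = y - q @ qty
    rss = float(resid @ resid)
    df = n - k
    return design, coef, r, rss, df


def wald_test(trait, genotype, covariates) -> AssociationResult:
    """Wald (t-based) test of the variant coefficient in the joint model."""
    g = np.asarray(genotype, dtype=float)
    if np.ptp(g) == 0.0:
        return AssociationResult(
            method="wald", statistic=0.0, p_value=1.0, flags=("degenerate_genotype",)
        )
    _, coef, r, rss, df = _joint_fit(trait, genotype, covariates)
    sigma2 = rss / df
    if sigma2 <= 0:
        return AssociationResult(
            method="wald", statistic=0.0, p_value=1.0, flags=("degenerate_fit",)
        )
    k = r.shape[0]
    e_last = np.zeros(k)
    e_last[-1] = 1.0
    # (R'R)^{-1}_{gg} = || R^{-T} e_g ||^2; g is the last column
    w = np.linalg.solve(r.T, e_last)
    se = float(np.sqrt(sigma2 * (w @ w)))
    beta = float(coef[-1])
    t = beta / se
    statistic = t * t
    p = float(2.0 * stats.t.sf(abs(t), df))
    return AssociationResult(
        method="wald", statistic=statistic, p_value=p, beta_hat=beta, se=se
    )


def partial_f_test(trait, genotype, covariates) -> AssociationResult:
    """Nested-model F test: covariates-only versus covariates + variant."""
    g = np.asarray(genotype, dtype=float)
    if np.ptp(g) == 0.0:
        return AssociationResult(
            method="partial_f", statistic=0.0, p_value=1.0, flags=("degenerate_genotype",)
        )
    null = fit_null(trait, covariates)
    sse_reduced = float(null.residuals @ null.residuals)
    _, coef, _, sse_full, df = _joint_fit(trait, genotype, covariates)
    if sse_full <= 0:
        return AssociationResult(
            method="partial_f", statistic=0.0, p_value=1.0, flags=("degenerate_fit",)
        )
    f = max(sse_reduced - sse_full, 0.0) / (sse_full / df)
    p = float(stats.f.sf(f, 1, df))
    return AssociationResult(
        method="partial_f", statistic=f, p_value=p, beta_hat=float(coef[-1])
    )
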