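"""Monte-Carlo engine for type-I-error and power studies.

Traits are generated from the linear model

    y_i = x_i1 * alpha1 + x_i2 * alpha2 + g_i * beta + eps_i

with a standard-normal continuous covariate ``x1``, a Bernoulli(1/2)
binary covariate ``x2``, and an additive genotype ``g_i ~ Binomial(2, p_i)``
whose allele frequency depends on ``x1`` through a logistic model

    p_i = expit(gamma0 + gamma1 * x_i1),

so ``gamma0`` sets how rare the variant is (-7: MAF 0.0009; -2: MAF
0.1192) and ``gamma1`` how strongly genotype is confounded with the
covariate.  Four error regimes are supported: normal (any sd), a 99/1
normal outlier mixture (sd 0.01 / sd 3), chi-squared with 2 df, and
gamma(0.1, 0.1).  The skewed error draws are used uncentered — the
analysis intercept absorbs their mean.  Generation has no intercept
term; the analysis design is always ``[1, x1, x2]``.

Replicates use counter-based RNG substreams spawned from the scenario
seed, so any single replicate is reproducible in isolation and results
do not depend on how the work is sharded across processes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from fsint.linmod import SampleData
from fsint.methods import METHODS, run_method

__all__ = [
    "ERROR_MODELS",
    "SimulationScenario",
    "RejectionRateEstimate",
    "genotype_prob",
    "generate_dataset",
    "estimate_rejection_rate",
    "expand_grid",
    "run_grid",
]

logger = logging.getLogger(__name__)

#: default parameters of each supported error regime
ERROR_MODELS = {
    "normal": {"sd": 1.0},
    "outlier_mixture": {"p_out": 0.01, "sd_main": 0.01, "sd_out": 3.0},
    "chisq": {"df": 2.0},
    "gamma": {"shape": 0.1, "scale": 0.1},
}


@dataclass(frozen=True)
class SimulationScenario:
    """Full generative parameterization of one simulation cell.

    Defaults follow the study design this engine reproduces: covariate
    effects ``alpha1 = alpha2 = 0.5``; ``beta = 0`` for type-I-error runs
    (0.0012 is the conventional power setting); nominal level 1e-4.
    """

    n: int = 2000
    gamma0: float = -7.0
    gamma1: float = 0.0
    alpha1: float = 0.5
    alpha2: float = 0.5
    beta: float = 0.0
    error_model: str = "normal"
    error_params: dict = field(default_factory=dict)
    nominal_alpha: float = 1e-4
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if not 0.0 < self.nominal_alpha < 1.0:
            raise ValueError("nominal_alpha must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.error_model not in ERROR_MODELS:
            raise ValueError(
                f"error_model must be one of {sorted(ERROR_MODELS)}; got {self.error_model!r}"
            )
        merged = dict(ERROR_MODELS[self.error_model])
        unknown = set(self.error_params) - set(merged)
        if unknown:
            raise ValueError(f"unknown error_params for {self.error_model}: {sorted(unknown)}")
        merged.update(self.error_params)
        object.__setattr__(self, "error_params", merged)


@dataclass(frozen=True)
class RejectionRateEstimate:
    """Empirical rejection proportion for one (method, scenario) cell."""

    method: str
    scenario: SimulationScenario
    rejections: int
    evaluated: int
    degenerate: int
    failures: int = 0

    @property
    def rate(self) -> float:
        return self.rejections / self.evaluated

    @property
    def mc_se(self) -> float:
        r = self.rate
        return math.sqrt(r * (1.0 - r) / self.evaluated)


def genotype_prob(gamma0: float, gamma1: float, x1) -> np.ndarray | float:
    """Per-individual allele frequency ``expit(gamma0 + gamma1 * x1)``."""
    return expit(gamma0 + gamma1 * np.asarray(x1, dtype=float))


def _draw_errors(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    n = scenario.n
    p = scenario.error_params
    model = scenario.error_model
    if model == "normal":
        return rng.normal(0.0, p["sd"], size=n)
    if model == "outlier_mixture":
        is_out = rng.random(n) < p["p_out"]
        sd = np.where(is_out, p["sd_out"], p["sd_main"])
        return rng.normal(0.0, 1.0, size=n) * sd
    if model == "chisq":
        return rng.chisquare(p["df"], size=n)
    if model == "gamma":
        return rng.gamma(p["shape"], p["scale"], size=n)
    raise AssertionError(f"unreachable error model {model!r}")


def generate_dataset(scenario: SimulationScenario, rng: np.random.Generator) -> SampleData:
    """Draw one replicate dataset under the scenario's generative model."""
    n = scenario.n
    x1 = rng.normal(0.0, 1.0, size=n)
    x2 = rng.integers(0, 2, size=n).astype(float)
    p = genotype_prob(scenario.gamma0, scenario.gamma1, x1)
    g = rng.binomial(2, p).astype(float)
    eps = _draw_errors(scenario, rng)
    y = scenario.alpha1 * x1 + scenario.alpha2 * x2 + scenario.beta * g + eps
    covariates = np.column_stack([np.ones(n), x1, x2])
    return SampleData(trait=y, covariates=covariates, genotype=g)


def _replicate_rngs(scenario: SimulationScenario):
    """Independent per-replicate substreams derived from the scenario seed."""
    ss = np.random.SeedSequence(scenario.seed)
    return ss.spawn(scenario.n_replicates)


def estimate_rejection_rate(
    method_key: str,
    scenario: SimulationScenario,
    max_failure_fraction: float = 0.01,
) -> RejectionRateEstimate:
    """Estimate the rejection rate of one method under one scenario.

    Every replicate contributes to the denominator: replicates with a
    monomorphic (degenerate) genotype, or where the method fails, count
    as non-rejections and are tallied separately so the alternative
    accounting can be recomputed.  A failure fraction above
    ``max_failure_fraction`` aborts the run.
    """
    if method_key not in METHODS:
        raise KeyError(f"unknown method {method_key!r}; choose from {sorted(METHODS)}")
    rejections = degenerate = failures = 0
    n_rep = scenario.n_replicates
    max_failures = max(1, int(max_failure_fraction * n_rep))
    for child in _replicate_rngs(scenario):
        rng = np.random.default_rng(child)
        data = generate_dataset(scenario, rng)
        # derived seed for any method-internal randomness, kept below 2^31
        method_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            result = run_method(method_key, data, seed=method_seed)
        except Exception:
            failures += 1
            logger.exception("method %s failed on a replicate", method_key)
            if failures > max_failures:
                raise RuntimeError(
                    f"method {method_key!r} failed on more than "
                    f"{max_failure_fraction:.0%} of replicates"
                )
            continue
        if "degenerate_genotype" in result.flags:
            degenerate += 1
            continue
        if result.p_value < scenario.nominal_alpha:
            rejections += 1
    return RejectionRateEstimate(
        method=method_key,
        scenario=scenario,
        rejections=rejections,
        evaluated=n_rep,
        degenerate=degenerate,
        failures=failures,
    )


def expand_grid(config: dict) -> list[SimulationScenario]:
    """Expand a grid configuration into concrete scenarios.

    ``config`` mirrors :class:`SimulationScenario` field names; any field
    given as a list becomes a grid axis (cartesian product).  Each cell
    receives a distinct deterministic seed derived from the base
    ``seed`` and its position in the expansion order.
    """
    from itertools import product

    base_seed = int(config.get("seed", 0))
    axes: dict[str, list] = {}
    fixed: dict[str, object] = {}
    for key, value in config.items():
        if key == "seed":
            continue
        if isinstance(value, (list, tuple)):
            axes[key] = list(value)
        else:
            fixed[key] = value
    keys = sorted(axes)
    scenarios = []
    combos = product(*(axes[k] for k in keys)) if keys else [()]
    for idx, combo in enumerate(combos):
        params = dict(fixed)
        params.update(dict(zip(keys, combo)))
        cell_seed = int(np.random.SeedSequence(base_seed, spawn_key=(idx,)).generate_state(1)[0] % (2**31))
        scenarios.append(SimulationScenario(seed=cell_seed, **params))
    return scenarios


def _cell_row(est: RejectionRateEstimate) -> dict:
    sc = est.scenario
    return {
        "method": est.method,
        "n": sc.n,
        "gamma0": sc.gamma0,
        "gamma1": sc.gamma1,
        "beta": sc.beta,
        "error_model": sc.error_model,
        "nominal_alpha": sc.nominal_alpha,
        "n_replicates": sc.n_replicates,
        "rejections": est.rejections,
        "evaluated": est.evaluated,
        "degenerate": est.degenerate,
        "rate": est.rate,
        "mc_se": est.mc_se,
        "seed": sc.seed,
    }


def run_grid(
    scenarios,
    methods,
    parallel_workers: int = 1,
    checkpoint_path=None,
    checkpoint_every: int = 8,
) -> pd.DataFrame:
    """Run every (scenario, method) cell and return a tidy results table.

    Each cell is fully determined by its scenario seed, so results are
    identical regardless of ``parallel_workers``.  With a
    ``checkpoint_path``, completed cells are appended to a CSV as the
    run progresses and are skipped on re-run (resume support).
    """
    cells = [(sc, m) for sc in scenarios for m in methods]
    done: set[tuple] = set()
    rows: list[dict] = []
    if checkpoint_path is not None:
        try:
            prior = pd.read_csv(checkpoint_path)
        except (FileNotFoundError, pd.errors.EmptyDataError):
            prior = None
        if prior is not None and len(prior):
            rows = prior.to_dict("records")
            done = {(int(r["seed"]), str(r["method"])) for r in rows}

    todo = [(sc, m) for sc, m in cells if (sc.seed, m) not in done]

    def _run(cell):
        sc, m = cell
        return _cell_row(estimate_rejection_rate(m, sc))

    if parallel_workers > 1 and len(todo) > 1:
        from joblib import Parallel, delayed

        for start in range(0, len(todo), checkpoint_every):
            chunk = todo[start : start + checkpoint_every]
            new_rows = Parallel(n_jobs=parallel_workers)(delayed(_run)(c) for c in chunk)
            rows.extend(new_rows)
            if checkpoint_path is not None:
                pd.DataFrame(rows).to_csv(checkpoint_path, index=False)
    else:
        for i, cell in enumerate(todo, 1):
            rows.append(_run(cell))
            if checkpoint_path is not None and (i % checkpoint_every == 0 or i == len(todo)):
                pd.DataFrame(rows).to_csv(checkpoint_path, index=False)

    frame = pd.DataFrame(rows)
    return frame.sort_values(["method", "n", "gamma0", "gamma1", "beta"]).reset_index(drop=True)
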