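"""Logistic-model outcome simulation and binary-outcome summary evaluators.

The data-generating process is a logistic regression on the frozen
super-population covariates,

    logit Pr(Y_i = 1) = b0 + g * Z_i + s * sum_j b_j * X_ij,

with intercept ``b0`` controlling outcome prevalence, treatment log-odds
ratio ``g`` controlling marginal treatment effects through the potential
outcomes Y(0)/Y(1), and the global coefficient scale ``s`` controlling the
model's discrimination (c-statistic) while preserving the ratio of any two
log-odds ratios.  The scale multiplies the covariate sum only, never the
intercept or the treatment term, which is why prevalence and c-statistic
calibrations interact.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .errors import DegenerateEstimandError, FitError, SpecificationError
from .superpop import SuperPopulation

__all__ = [
    "LogisticModelSpec",
    "LogisticFit",
    "linear_predictor",
    "simulate_binary_outcomes",
    "empirical_prevalence",
    "simulate_treatment",
    "potential_binary_outcomes",
    "marginal_relative_risk",
    "marginal_risk_difference",
    "fit_logistic_mle",
    "c_statistic",
]


@dataclasses.dataclass(frozen=True, eq=False)
class LogisticModelSpec:
    """Coefficients of the outcome (or treatment-assignment) logistic model.

    ``intercept`` and ``coefficients`` are on the log-odds(-ratio) scale;
    ``treatment_log_or`` is the conditional treatment log-odds ratio (0 for a
    treatment-assignment model); ``scale`` is the dimensionless multiplier
    applied to the covariate sum only.
    """

    intercept: float
    coefficients: np.ndarray
    treatment_log_or: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        coef = np.atleast_1d(np.asarray(self.coefficients, dtype=np.float64))
        if coef.ndim != 1:
            raise SpecificationError("coefficients must be a 1-D vector")
        if not np.isfinite(coef).all():
            raise SpecificationError("coefficients must be finite")
        if not self.scale >= 0:
            raise SpecificationError("scale must be >= 0")
        object.__setattr__(self, "coefficients", coef)


def _as_indicator(values, name: str, n: int | None = None) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise SpecificationError(f"{name} must be a 1-D vector")
    if n is not None and arr.shape[0] != n:
        raise SpecificationError(f"{name} has length {arr.shape[0]}, expected {n}")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise SpecificationError(f"{name} entries must be 0/1")
    return arr.astype(np.float64)


def linear_predictor(
    population: SuperPopulation,
    spec: LogisticModelSpec,
    treatment: np.ndarray | None = None,
) -> np.ndarray:
    """Per-subject log-odds: b0 + g*Z_i + scale * sum_j b_j X_ij.

    The treatment term is omitted when ``treatment`` is None.
    """
    if spec.coefficients.shape[0] != population.n_covariates:
        raise SpecificationError(
            f"{spec.coefficients.shape[0]} coefficients for "
            f"{population.n_covariates} covariate columns"
        )
    lp = spec.intercept + spec.scale * (population.values @ spec.coefficients)
    if treatment is not None:
        z = _as_indicator(treatment, "treatment", population.n)
        lp = lp + spec.treatment_log_or * z
    return lp


def simulate_binary_outcomes(linear_predictor: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw Y_i ~ Bernoulli(inverse-logit(lp_i)), independently within the stream."""
    lp = np.asarray(linear_predictor, dtype=np.float64)
    if not np.isfinite(lp).all():
        raise SpecificationError("linear predictor must be finite")
    p = expit(lp)
    return (rng.random(lp.shape[0]) < p).astype(np.int8)


def empirical_prevalence(outcomes: np.ndarray) -> float:
    """Proportion of 1s among the simulated outcomes."""
    y = _as_indicator(outcomes, "outcomes")
    if y.size == 0:
        raise SpecificationError("outcomes vector is empty")
    return float(y.mean())


def simulate_treatment(
    population: SuperPopulation,
    treatment_model: LogisticModelSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign treatment from a logistic selection model on the covariates.

    The selection model must not itself contain a treatment term; treatment
    prevalence is governed by its intercept.
    """
    if treatment_model.treatment_log_or != 0.0:
        raise SpecificationError("a treatment-assignment model must have treatment_log_or = 0")
    lp = linear_predictor(population, treatment_model, treatment=None)
    return simulate_binary_outcomes(lp, rng)


def potential_binary_outcomes(
    population: SuperPopulation,
    spec: LogisticModelSpec,
    rng: np.random.Generator,
    shared_uniforms: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the potential outcomes Y(0) (Z≡0) and Y(1) (Z≡1) for everyone.

    Both arms use the same super-population and model; the arms draw
    independent uniforms by default, or compare one shared uniform panel
    against both arms' probabilities when ``shared_uniforms`` is True (common
    random numbers across arms).
    """
    lp0 = linear_predictor(population, spec, treatment=None)
    p0 = expit(lp0)
    p1 = expit(lp0 + spec.treatment_log_or)
    if shared_uniforms:
        u = rng.random(population.n)
        return (u < p0).astype(np.int8), (u < p1).astype(np.int8)
    y0 = (rng.random(population.n) < p0).astype(np.int8)
    y1 = (rng.random(population.n) < p1).astype(np.int8)
    return y0, y1


def marginal_relative_risk(y0: np.ndarray, y1: np.ndarray) -> float:
    """Population-average relative risk E[Y(1)] / E[Y(0)]."""
    m0 = empirical_prevalence(y0)
    m1 = empirical_prevalence(y1)
    if m0 == 0.0:
        raise DegenerateEstimandError("control-arm risk is zero; relative risk undefined")
    return m1 / m0


def marginal_risk_difference(y0: np.ndarray, y1: np.ndarray) -> float:
    """Average treatment effect E[Y(1) - Y(0)]."""
    a0 = _as_indicator(y0, "y0")
    a1 = _as_indicator(y1, "y1", a0.shape[0])
    return float(a1.mean() - a0.mean())


@dataclasses.dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit: intercept-first coefficients and SEs."""

    params: np.ndarray
    bse: np.ndarray
    n_iterations: int
    converged: bool

    def predict_linear(self, population: SuperPopulation) -> np.ndarray:
        return self.params[0] + population.values @ self.params[1:]


def fit_logistic_mle(
    population: SuperPopulation,
    outcomes: np.ndarray,
    convergence_tolerance: float | None = None,
    max_newton_steps: int = 50,
) -> LogisticFit:
    """Fit the logistic regression of outcomes on all covariates by IRLS.

    Convergence is declared when the maximum absolute score (gradient)
    component falls below ``convergence_tolerance`` (default ``1e-8 * N``,
    scaling with the sample because the score is a sum over subjects).
    Newton steps are halved whenever they would decrease the log-likelihood.
    Single-class outcomes, or a coefficient norm diverging beyond 40 on the
    log-odds scale (complete separation), raise :class:`FitError`.
    """
    y = _as_indicator(outcomes, "outcomes", population.n)
    if y.min() == y.max():
        raise FitError("outcomes contain a single class; logistic MLE undefined")
    n = population.n
    tol = 1e-8 * n if convergence_tolerance is None else float(convergence_tolerance)

    X = np.column_stack([np.ones(n), population.values])
    beta = np.zeros(X.shape[1])
    eta = X @ beta
    loglik = float(y @ eta - np.logaddexp(0.0, eta).sum())
    converged = False
    it = 0
    for it in range(1, int(max_newton_steps) + 1):
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.abs(score).max() <= tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        hessian = (X * w[:, None]).T @ X
        step = np.linalg.solve(hessian, score)
        # step-halving safeguard
        for _ in range(30):
            candidate = beta + step
            eta_new = X @ candidate
            loglik_new = float(y @ eta_new - np.logaddexp(0.0, eta_new).sum())
            if loglik_new >= loglik - 1e-10:
                break
            step = 0.5 * step
        beta, eta, loglik = candidate, eta_new, loglik_new
        if np.abs(beta).max() > 40.0 or not np.isfinite(beta).all():
            raise FitError("coefficients diverging; data likely separated")
    if not converged:
        raise FitError(f"IRLS did not converge within {max_newton_steps} steps")

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    covariance = np.linalg.inv((X * w[:, None]).T @ X)
    return LogisticFit(
        params=beta,
        bse=np.sqrt(np.diag(covariance)),
        n_iterations=it,
        converged=True,
    )


def c_statistic(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Concordance (AUC): Pr(random case score > random control score), ties half.

    Computed from rank sums in O(N log N); equals the area under the ROC
    curve of the score.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = _as_indicator(outcomes, "outcomes", s.shape[0])
    n1 = int(y.sum())
    n0 = y.shape[0] - n1
    if n0 == 0 or n1 == 0:
        raise DegenerateEstimandError("c-statistic undefined with a single outcome class")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))
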