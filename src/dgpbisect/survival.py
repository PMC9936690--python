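"""Inverse-CDF time-to-event simulation and the marginal hazard-ratio evaluator.

Event times follow a proportional-hazards model

    log h_i(t) = log h_0(t) + g * Z_i + sum_j b_j * X_ij,

simulated by inverting the cumulative hazard (the standard inverse-CDF
construction for proportional-hazards data): with U ~ Uniform(0, 1) and an
exponential or Weibull baseline with rate ``lam`` and shape ``nu``,

    T = (-log U / (lam * exp(LP)))**(1 / nu).

The marginal (population-average) hazard ratio for treatment is estimated by
concatenating the two potential-outcome time vectors T(0) (Z≡0 for all) and
T(1) (Z≡1 for all) with an arm indicator and fitting a univariate Cox model.
Because hazard ratios are non-collapsible, the marginal HR is attenuated
toward 1 relative to the conditional g whenever covariate effects are
nonzero, and with no censoring its estimate depends only on the ordering of
event times — hence it is invariant to the baseline-hazard parameters.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .errors import ConvergenceError, SpecificationError
from .superpop import SuperPopulation

__all__ = [
    "SurvivalModelSpec",
    "CoxFit",
    "bender_event_times",
    "potential_event_times",
    "fit_cox_univariate",
    "marginal_hazard_ratio",
]

BASELINE_FAMILIES = ("exponential", "weibull")


@dataclasses.dataclass(frozen=True, eq=False)
class SurvivalModelSpec:
    """Proportional-hazards DGP: baseline family plus log-hazard-ratio coefficients.

    ``rate`` (lam > 0) scales the baseline hazard; ``shape`` (nu > 0) is the
    Weibull shape, fixed at 1 for the exponential family.  ``coefficients``
    are covariate log-hazard ratios and ``treatment_log_hr`` the conditional
    treatment log-hazard ratio g (hazard increasing in g, so a protective
    treatment has g < 0).
    """

    coefficients: np.ndarray
    treatment_log_hr: float = 0.0
    baseline_family: str = "exponential"
    rate: float = 1.0
    shape: float = 1.0

    def __post_init__(self) -> None:
        coef = np.atleast_1d(np.asarray(self.coefficients, dtype=np.float64))
        if coef.ndim != 1 or not np.isfinite(coef).all():
            raise SpecificationError("coefficients must be a finite 1-D vector")
        if self.baseline_family not in BASELINE_FAMILIES:
            raise SpecificationError(
                f"baseline_family must be one of {BASELINE_FAMILIES}, got {self.baseline_family!r}"
            )
        if not self.rate > 0:
            raise SpecificationError("rate must be > 0")
        if not self.shape > 0:
            raise SpecificationError("shape must be > 0")
        if self.baseline_family == "exponential" and self.shape != 1.0:
            raise SpecificationError("exponential baseline requires shape = 1")
        object.__setattr__(self, "coefficients", coef)


def bender_event_times(
    population: SuperPopulation,
    treatment: np.ndarray | int | None,
    spec: SurvivalModelSpec,
    uniforms: np.ndarray,
) -> np.ndarray:
    """Event times from the inverse cumulative hazard, one per subject.

    ``treatment`` may be a 0/1 vector, a scalar arm indicator applied to all
    subjects (the potential-outcomes construction), or None (no treatment
    term).  Larger linear predictors yield stochastically shorter times.
    Uniforms must lie strictly inside (0, 1).
    """
    u = np.asarray(uniforms, dtype=np.float64)
    if u.shape != (population.n,):
        raise SpecificationError(f"uniforms have shape {u.shape}, expected ({population.n},)")
    if not ((u > 0.0) & (u < 1.0)).all():
        raise SpecificationError("uniforms must lie strictly inside (0, 1)")
    if spec.coefficients.shape[0] != population.n_covariates:
        raise SpecificationError(
            f"{spec.coefficients.shape[0]} coefficients for "
            f"{population.n_covariates} covariate columns"
        )
    lp = population.values @ spec.coefficients
    if treatment is not None:
        z = np.broadcast_to(np.asarray(treatment, dtype=np.float64), (population.n,))
        if not np.isin(np.unique(z), (0.0, 1.0)).all():
            raise SpecificationError("treatment entries must be 0/1")
        lp = lp + spec.treatment_log_hr * z
    cumulative_hazard = -np.log(u)
    return (cumulative_hazard / (spec.rate * np.exp(lp))) ** (1.0 / spec.shape)


def potential_event_times(
    population: SuperPopulation,
    spec: SurvivalModelSpec,
    rng: np.random.Generator,
    shared_uniforms: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Potential event times T(0) (Z≡0) and T(1) (Z≡1) for every subject.

    Arms use independent uniform panels by default, or one shared panel
    (common random numbers) when ``shared_uniforms`` is True, in which case
    with an exponential baseline T(1) = T(0) * exp(-g) elementwise.
    """

    def draw(n: int) -> np.ndarray:
        u = rng.random(n)
        # rng.random is in [0, 1); shift exact zeros off the boundary
        return np.where(u == 0.0, np.finfo(np.float64).tiny, u)

    u0 = draw(population.n)
    u1 = u0 if shared_uniforms else draw(population.n)
    t0 = bender_event_times(population, 0, spec, u0)
    t1 = bender_event_times(population, 1, spec, u1)
    return t0, t1


@dataclasses.dataclass(frozen=True)
class CoxFit:
    """Univariate Cox partial-likelihood fit for a binary covariate."""

    log_hr: float
    se: float
    n_iterations: int
    converged: bool

    @property
    def hazard_ratio(self) -> float:
        return math.exp(self.log_hr)


def _breslow_sufficient_stats(times: np.ndarray, group: np.ndarray):
    """Per-event-time counts: events d, treated events d1, at-risk r0/r1."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    z = group[order]
    n = t.shape[0]
    _, start = np.unique(t, return_index=True)
    counts = np.diff(np.append(start, n))
    cumz = np.concatenate([[0.0], np.cumsum(z)])
    d1 = cumz[start + counts] - cumz[start]
    treated_total = cumz[-1]
    r1 = treated_total - cumz[start]  # treated still at risk at each event time
    r_total = n - start
    r0 = r_total - r1
    return counts.astype(np.float64), d1, r0, r1, treated_total


def fit_cox_univariate(
    times: np.ndarray,
    group: np.ndarray,
    convergence_tolerance: float | None = None,
    max_iterations: int = 60,
) -> CoxFit:
    """Maximize the Cox partial likelihood for a single binary covariate.

    Uses safeguarded Newton iteration (step-halving on log-likelihood
    decrease) with the Breslow convention for tied event times; all records
    are treated as events (the calibration recipes generate uncensored
    data).  Convergence is declared when |score| <= ``convergence_tolerance``
    (default ``1e-9 * number of events``, scaling with the sample since the
    score is a sum over events).  A log-hazard ratio escaping beyond ±50
    signals a monotone partial likelihood (one group's times entirely
    preceding the other's) and raises :class:`ConvergenceError`.
    """
    t = np.asarray(times, dtype=np.float64)
    z = np.asarray(group, dtype=np.float64)
    if t.ndim != 1 or z.shape != t.shape:
        raise SpecificationError("times and group must be 1-D vectors of equal length")
    if not np.isin(np.unique(z), (0.0, 1.0)).all():
        raise SpecificationError("group entries must be 0/1")
    if z.min() == z.max():
        raise SpecificationError("both groups must be present")
    if np.unique(t).shape[0] < 2:
        raise SpecificationError("at least two distinct event times are required")
    if not (t > 0).all():
        raise SpecificationError("event times must be positive")

    d, d1, r0, r1, treated_events = _breslow_sufficient_stats(t, z)
    total_treated_events = float(d1.sum())
    tol = 1e-9 * t.shape[0] if convergence_tolerance is None else float(convergence_tolerance)

    # The score is decreasing in g (concave log-likelihood), so the likelihood
    # is monotone -- no interior maximum -- iff the score keeps one sign in the
    # limit: score(+inf) = D1 - sum(d at times with any treated at risk),
    # score(-inf) = D1 - sum(d at times where only treated remain at risk).
    if total_treated_events - float(d[r1 > 0].sum()) >= 0.0:
        raise ConvergenceError(
            "monotone partial likelihood: every event with a treated subject at risk "
            "is a treated event; the log-hazard ratio increases without bound"
        )
    if total_treated_events - float(d[r0 == 0].sum()) <= 0.0:
        raise ConvergenceError(
            "monotone partial likelihood: the log-hazard ratio decreases without bound"
        )

    def loglik(g: float) -> float:
        denom = r0 + math.exp(g) * r1
        return g * total_treated_events - float(d @ np.log(denom))

    def score_info(g: float) -> tuple[float, float]:
        e = math.exp(g)
        denom = r0 + e * r1
        frac = e * r1 / denom
        score = total_treated_events - float(d @ frac)
        info = float(d @ (frac * (r0 / denom)))
        return score, info

    g = 0.0
    ll = loglik(g)
    converged = False
    it = 0
    for it in range(1, int(max_iterations) + 1):
        score, info = score_info(g)
        if abs(score) <= tol:
            converged = True
            break
        if info <= 0.0 or not math.isfinite(info):
            raise ConvergenceError("vanishing partial-likelihood information; fit is degenerate")
        step = score / info
        # step-halving: tolerate log-likelihood jitter at float resolution,
        # which scales with |loglik| on large concatenated datasets
        slack = 1e-9 * max(1.0, abs(ll))
        for _ in range(40):
            candidate = g + step
            ll_new = loglik(candidate)
            if math.isfinite(ll_new) and ll_new >= ll - slack:
                break
            step *= 0.5
        g, ll = candidate, ll_new
        if abs(step) < 1e-14 * (1.0 + abs(g)):
            converged = True
            break
        if abs(g) > 50.0:
            raise ConvergenceError(
                "log-hazard ratio diverging; the partial likelihood is monotone "
                "(one group's event times entirely precede the other's)"
            )
    if not converged:
        raise ConvergenceError(f"Cox Newton iteration did not converge within {max_iterations} steps")

    _, info = score_info(g)
    return CoxFit(log_hr=g, se=1.0 / math.sqrt(info), n_iterations=it, converged=True)


def marginal_hazard_ratio(t0: np.ndarray, t1: np.ndarray) -> float:
    """Marginal HR: univariate Cox fit on the concatenated potential outcomes.

    The 2N records (all events) are stacked with an arm indicator (0 for the
    control arm T(0), 1 for the treated arm T(1)) and the exponentiated Cox
    coefficient on the arm indicator is returned.
    """
    a0 = np.asarray(t0, dtype=np.float64)
    a1 = np.asarray(t1, dtype=np.float64)
    if a0.shape != a1.shape or a0.ndim != 1:
        raise SpecificationError("potential-outcome time vectors must be 1-D and of equal length")
    times = np.concatenate([a0, a1])
    arm = np.concatenate([np.zeros(a0.shape[0]), np.ones(a1.shape[0])])
    return fit_cox_univariate(times, arm).hazard_ratio
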