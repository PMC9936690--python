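"""End-to-end calibration recipes for the four built-in scenarios.

Each recipe freezes one super-population of baseline covariates, wraps the
appropriate summary evaluator (outcome prevalence, marginal relative risk or
risk difference, model c-statistic, marginal hazard ratio), and drives the
bisection engine toward the target.  ``default_paper_configs`` returns the
reference parameterizations: ten covariates (five standard normal, five
Bernoulli(0.5)), outcome log-odds/log-hazard ratios log(1.25), log(1.5),
log(1.75), log(2), log(2.5) repeated twice, treatment-selection coefficients
log(1.1), log(2), log(3), log(1.5), log(1.5) repeated twice, N = 10⁶.

The relative-risk and hazard-ratio recipes are chained: the
treatment-selection intercept is first calibrated so treatment prevalence is
0.20, and the outcome intercept so the untreated outcome prevalence is 0.10;
each stage's calibrated value is injected into the next stage's config.  The
default configs carry the values those stage calibrations produce at N = 10⁶
so every scenario is runnable standalone.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Callable, Mapping
from pathlib import Path

import numpy as np

from .binary import (
    LogisticModelSpec,
    c_statistic,
    empirical_prevalence,
    fit_logistic_mle,
    marginal_relative_risk,
    marginal_risk_difference,
    potential_binary_outcomes,
    simulate_binary_outcomes,
)
from .bisection import (
    BisectionProblem,
    BisectionSettings,
    Bracket,
    CalibrationResult,
    SeedPolicy,
    SequentialCalibrationResult,
    bisect_calibrate,
    sequential_calibrate,
    write_trace,
)
from .errors import SpecificationError
from .superpop import CovariateSpec, SuperPopulation, generate_superpopulation
from .survival import SurvivalModelSpec, marginal_hazard_ratio, potential_event_times

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "run_scenario",
    "default_paper_configs",
    "scenario_config_from_dict",
    "prevalence_evaluator",
    "relative_risk_evaluator",
    "risk_difference_evaluator",
    "c_statistic_evaluator",
    "marginal_hazard_ratio_evaluator",
    "OUTCOME_LOG_ODDS_RATIOS",
    "TREATMENT_LOG_ODDS_RATIOS",
]

SCENARIOS = (
    "prevalence",
    "relative_risk",
    "risk_difference",
    "c_statistic",
    "marginal_hazard_ratio",
    "joint",
)

# Reference coefficient sets (log odds/hazard ratios) for the built-in scenarios.
OUTCOME_LOG_ODDS_RATIOS = tuple(math.log(o) for o in (1.25, 1.5, 1.75, 2.0, 2.5) * 2)
TREATMENT_LOG_ODDS_RATIOS = tuple(math.log(o) for o in (1.1, 2.0, 3.0, 1.5, 1.5) * 2)

# Calibrated stage values at N = 10⁶ (reproducible with run_scenario), used to
# seed the chained default configs so each scenario runs standalone.
DEFAULT_OUTCOME_INTERCEPT = -4.368896  # untreated outcome prevalence 0.10
DEFAULT_RR_OUTCOME_INTERCEPT = -4.367676  # intercept injected into the relative-risk recipe
DEFAULT_TREATMENT_INTERCEPT = -3.31749  # treatment prevalence 0.20
DEFAULT_RR_LOG_OR = -0.2999878  # marginal relative risk 0.80
DEFAULT_CSTAT_SCALE = 0.8349609  # c-statistic 0.80
DEFAULT_MARGINAL_HR_LOG_HR = -0.6298828  # marginal hazard ratio 0.80 (protective)

# Default stopping tolerances per summary (the parameter-scale error this
# allows stays well inside each scenario's reporting precision; see docs).
DEFAULT_TOLERANCES = {
    "prevalence": 5e-4,
    "relative_risk": 1e-3,
    "risk_difference": 5e-4,
    "c_statistic": 1e-3,
    "marginal_hazard_ratio": 1e-3,
}


# ---------------------------------------------------------------------------
# Summary evaluators (parameter, rng) -> summary
# ---------------------------------------------------------------------------


def prevalence_evaluator(
    population: SuperPopulation, model: LogisticModelSpec
) -> Callable[[float, np.random.Generator], float]:
    """Evaluator mapping an intercept to the empirical outcome prevalence.

    Works for outcome models and treatment-assignment models alike; the
    covariate contribution is precomputed once against the frozen population.
    """
    xb = model.scale * (population.values @ model.coefficients)

    def evaluate(intercept: float, rng: np.random.Generator) -> float:
        y = simulate_binary_outcomes(intercept + xb, rng)
        return empirical_prevalence(y)

    return evaluate


def relative_risk_evaluator(
    population: SuperPopulation,
    outcome_model: LogisticModelSpec,
    shared_uniforms: bool = False,
) -> Callable[[float, np.random.Generator], float]:
    """Evaluator mapping the treatment log-odds ratio to the marginal RR."""

    def evaluate(gamma: float, rng: np.random.Generator) -> float:
        spec = dataclasses.replace(outcome_model, treatment_log_or=gamma)
        y0, y1 = potential_binary_outcomes(population, spec, rng, shared_uniforms)
        return marginal_relative_risk(y0, y1)

    return evaluate


def risk_difference_evaluator(
    population: SuperPopulation,
    outcome_model: LogisticModelSpec,
    shared_uniforms: bool = False,
) -> Callable[[float, np.random.Generator], float]:
    """Evaluator mapping the treatment log-odds ratio to the marginal RD."""

    def evaluate(gamma: float, rng: np.random.Generator) -> float:
        spec = dataclasses.replace(outcome_model, treatment_log_or=gamma)
        y0, y1 = potential_binary_outcomes(population, spec, rng, shared_uniforms)
        return marginal_risk_difference(y0, y1)

    return evaluate


def c_statistic_evaluator(
    population: SuperPopulation,
    outcome_model: LogisticModelSpec,
    use_fitted_model: bool = True,
) -> Callable[[float, np.random.Generator], float]:
    """Evaluator mapping the coefficient scale to the model c-statistic.

    By default a logistic model is refitted to each simulated sample and its
    c-statistic evaluated, mirroring how the statistic would be measured in
    practice; ``use_fitted_model=False`` scores with the true linear
    predictor instead (asymptotically equivalent at large N, and much
    faster since it skips the fit).
    """
    xb = population.values @ outcome_model.coefficients

    def evaluate(scale: float, rng: np.random.Generator) -> float:
        lp = outcome_model.intercept + scale * xb
        y = simulate_binary_outcomes(lp, rng)
        scores = fit_logistic_mle(population, y).predict_linear(population) if use_fitted_model else lp
        return c_statistic(scores, y)

    return evaluate


def marginal_hazard_ratio_evaluator(
    population: SuperPopulation,
    survival_model: SurvivalModelSpec,
    shared_uniforms: bool = False,
) -> Callable[[float, np.random.Generator], float]:
    """Evaluator mapping the conditional log-HR to the marginal hazard ratio."""

    def evaluate(gamma: float, rng: np.random.Generator) -> float:
        spec = dataclasses.replace(survival_model, treatment_log_hr=gamma)
        t0, t1 = potential_event_times(population, spec, rng, shared_uniforms)
        return marginal_hazard_ratio(t0, t1)

    return evaluate


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass(eq=False)
class ScenarioConfig:
    """Everything needed to run one calibration scenario end to end."""

    scenario: str
    covariates: CovariateSpec
    target_value: float
    bracket: Bracket
    outcome_model: LogisticModelSpec | SurvivalModelSpec | None = None
    treatment_model: LogisticModelSpec | None = None
    settings: BisectionSettings = dataclasses.field(default_factory=BisectionSettings)
    seed: int = 0
    shared_uniforms: bool = False
    common_random_numbers: bool = False
    score_with_true_model: bool = False
    # joint scenario only: the second (c-statistic) characteristic
    secondary_target_value: float | None = None
    secondary_bracket: Bracket | None = None
    outer_max: int = 5

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise SpecificationError(f"scenario: must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.scenario == "marginal_hazard_ratio":
            if not isinstance(self.outcome_model, SurvivalModelSpec):
                raise SpecificationError("outcome_model: marginal_hazard_ratio requires a SurvivalModelSpec")
        elif not isinstance(self.outcome_model, LogisticModelSpec):
            raise SpecificationError(f"outcome_model: {self.scenario} requires a LogisticModelSpec")
        if self.scenario in ("prevalence", "c_statistic", "joint"):
            if not 0.0 < self.target_value < 1.0:
                raise SpecificationError(
                    f"target_value: a {'prevalence' if self.scenario != 'c_statistic' else 'c-statistic'} "
                    f"target must lie in (0, 1), got {self.target_value}"
                )
        elif self.scenario in ("relative_risk", "marginal_hazard_ratio"):
            if not self.target_value > 0.0:
                raise SpecificationError(f"target_value: a ratio target must be > 0, got {self.target_value}")
        elif self.scenario == "risk_difference":
            if not -1.0 < self.target_value < 1.0:
                raise SpecificationError(
                    f"target_value: a risk-difference target must lie in (-1, 1), got {self.target_value}"
                )
        if self.scenario == "joint":
            if self.secondary_target_value is None or self.secondary_bracket is None:
                raise SpecificationError(
                    "secondary_target_value/secondary_bracket: required for the joint scenario"
                )
            if not 0.0 < self.secondary_target_value < 1.0:
                raise SpecificationError(
                    f"secondary_target_value: a c-statistic target must lie in (0, 1), "
                    f"got {self.secondary_target_value}"
                )
        if self.treatment_model is not None and self.treatment_model.treatment_log_or != 0.0:
            raise SpecificationError("treatment_model: must have treatment_log_or = 0")


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence((int(seed), *key)).generate_state(1)[0])


def run_scenario(
    config: ScenarioConfig,
    trace_path: str | Path | None = None,
) -> CalibrationResult | SequentialCalibrationResult:
    """Run one calibration scenario: build the super-population once, wrap the
    scenario's evaluator, bisect, and optionally write the trace file.

    For ``scenario="joint"`` the outcome intercept (prevalence target) and
    coefficient scale (c-statistic target) are calibrated sequentially and a
    :class:`SequentialCalibrationResult` is returned; per-problem traces are
    written to ``<stem>_<parameter><suffix>``.
    """
    config.validate()
    population = generate_superpopulation(config.covariates, seed=_child_seed(config.seed, 0))
    policy = SeedPolicy(_child_seed(config.seed, 1), config.common_random_numbers)

    if config.scenario == "joint":
        result = _run_joint(config, population, policy)
        if trace_path is not None:
            p = Path(trace_path)
            for name, sub in result.as_dict().items():
                write_trace(sub, p.with_name(f"{p.stem}_{name}{p.suffix}"))
        return result

    if config.scenario == "prevalence":
        evaluator = prevalence_evaluator(population, config.outcome_model)
    elif config.scenario == "relative_risk":
        evaluator = relative_risk_evaluator(population, config.outcome_model, config.shared_uniforms)
    elif config.scenario == "risk_difference":
        evaluator = risk_difference_evaluator(population, config.outcome_model, config.shared_uniforms)
    elif config.scenario == "c_statistic":
        evaluator = c_statistic_evaluator(
            population, config.outcome_model, use_fitted_model=not config.score_with_true_model
        )
    else:  # marginal_hazard_ratio
        evaluator = marginal_hazard_ratio_evaluator(
            population, config.outcome_model, config.shared_uniforms
        )

    result = bisect_calibrate(evaluator, config.target_value, config.bracket, config.settings, policy)
    if trace_path is not None:
        write_trace(result, trace_path)
    return result


def _run_joint(
    config: ScenarioConfig,
    population: SuperPopulation,
    policy: SeedPolicy,
) -> SequentialCalibrationResult:
    """Sequentially calibrate intercept (prevalence) and scale (c-statistic)."""
    model = config.outcome_model
    xb = population.values @ model.coefficients

    def prevalence_of(intercept: float, frozen: Mapping[str, float], rng: np.random.Generator) -> float:
        y = simulate_binary_outcomes(intercept + frozen["scale"] * xb, rng)
        return empirical_prevalence(y)

    def cstat_of(scale: float, frozen: Mapping[str, float], rng: np.random.Generator) -> float:
        lp = frozen["intercept"] + scale * xb
        y = simulate_binary_outcomes(lp, rng)
        if config.score_with_true_model:
            scores = lp
        else:
            scores = fit_logistic_mle(population, y).predict_linear(population)
        return c_statistic(scores, y)

    problems = [
        BisectionProblem(
            name="intercept",
            evaluator=prevalence_of,
            target=config.target_value,
            bracket=config.bracket,
            settings=dataclasses.replace(
                config.settings, summary_tolerance=DEFAULT_TOLERANCES["prevalence"]
            )
            if config.settings.summary_tolerance == 0.0
            else config.settings,
            initial=model.intercept,
        ),
        BisectionProblem(
            name="scale",
            evaluator=cstat_of,
            target=config.secondary_target_value,
            bracket=config.secondary_bracket,
            settings=dataclasses.replace(
                config.settings, summary_tolerance=DEFAULT_TOLERANCES["c_statistic"]
            )
            if config.settings.summary_tolerance == 0.0
            else config.settings,
            initial=model.scale,
        ),
    ]
    return sequential_calibrate(problems, outer_max=config.outer_max, seed_policy=policy)


# ---------------------------------------------------------------------------
# Reference configurations
# ---------------------------------------------------------------------------


def default_paper_configs(
    population_size: int = 1_000_000,
    seed: int = 0,
) -> dict[str, ScenarioConfig]:
    """Ready-to-run configs for the built-in scenarios at their reference targets.

    Keys: ``prevalence`` (outcome prevalence 0.10), ``treatment_prevalence``
    (treatment prevalence 0.20), ``relative_risk`` (marginal RR 0.80),
    ``risk_difference`` (marginal RD -0.02, i.e. RR 0.80 at baseline risk
    0.10), ``c_statistic`` (AUC 0.80), ``marginal_hazard_ratio`` (marginal
    HR 0.80), and ``joint`` (prevalence 0.10 plus c-statistic 0.80).
    Chained upstream values (treatment and outcome intercepts) are pre-filled
    with their calibrated N=10⁶ values.
    """
    covariates = CovariateSpec(5, 5, 0.5, population_size)
    outcome = LogisticModelSpec(intercept=DEFAULT_OUTCOME_INTERCEPT, coefficients=OUTCOME_LOG_ODDS_RATIOS)
    treatment = LogisticModelSpec(
        intercept=DEFAULT_TREATMENT_INTERCEPT, coefficients=TREATMENT_LOG_ODDS_RATIOS
    )

    def settings(kind: str) -> BisectionSettings:
        return BisectionSettings(max_iterations=25, summary_tolerance=DEFAULT_TOLERANCES[kind])

    configs = {
        "prevalence": ScenarioConfig(
            scenario="prevalence",
            covariates=covariates,
            target_value=0.10,
            bracket=Bracket(-10.0, 10.0),
            outcome_model=outcome,
            settings=settings("prevalence"),
            seed=seed,
        ),
        "treatment_prevalence": ScenarioConfig(
            scenario="prevalence",
            covariates=covariates,
            target_value=0.20,
            bracket=Bracket(-10.0, 10.0),
            outcome_model=treatment,
            settings=settings("prevalence"),
            seed=seed,
        ),
        "relative_risk": ScenarioConfig(
            scenario="relative_risk",
            covariates=covariates,
            target_value=0.80,
            bracket=Bracket(-10.0, 10.0),
            outcome_model=dataclasses.replace(outcome, intercept=DEFAULT_RR_OUTCOME_INTERCEPT),
            treatment_model=treatment,
            settings=settings("relative_risk"),
            seed=seed,
        ),
        "risk_difference": ScenarioConfig(
            scenario="risk_difference",
            covariates=covariates,
            target_value=-0.02,
            bracket=Bracket(-10.0, 10.0),
            outcome_model=dataclasses.replace(outcome, intercept=DEFAULT_RR_OUTCOME_INTERCEPT),
            treatment_model=treatment,
            settings=settings("risk_difference"),
            seed=seed,
        ),
        "c_statistic": ScenarioConfig(
            scenario="c_statistic",
            covariates=covariates,
            target_value=0.80,
            bracket=Bracket(0.0, 10.0),
            outcome_model=outcome,
            settings=settings("c_statistic"),
            seed=seed,
        ),
        "marginal_hazard_ratio": ScenarioConfig(
            scenario="marginal_hazard_ratio",
            covariates=covariates,
            target_value=0.80,
            bracket=Bracket(-10.0, 10.0),
            outcome_model=SurvivalModelSpec(
                coefficients=OUTCOME_LOG_ODDS_RATIOS, baseline_family="exponential", rate=1.0, shape=1.0
            ),
            treatment_model=treatment,
            settings=settings("marginal_hazard_ratio"),
            seed=seed,
        ),
        "joint": ScenarioConfig(
            scenario="joint",
            covariates=covariates,
            target_value=0.10,
            bracket=Bracket(-10.0, 10.0),
            outcome_model=outcome,
            settings=BisectionSettings(max_iterations=25, summary_tolerance=0.0),
            seed=seed,
            secondary_target_value=0.80,
            secondary_bracket=Bracket(0.0, 10.0),
        ),
    }
    for config in configs.values():
        config.validate()
    return configs


# ---------------------------------------------------------------------------
# Structured-text configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "target",
    "target_value",
    "bracket",
    "tolerance",
    "max_iterations",
    "seed",
    "population_size",
    "n_continuous",
    "n_binary",
    "binary_p",
    "outcome_coefficients",
    "outcome_intercept",
    "outcome_scale",
    "treatment_coefficients",
    "treatment_intercept",
    "baseline_family",
    "baseline_rate",
    "baseline_shape",
    "shared_uniforms",
    "common_random_numbers",
    "score_with_true_model",
    "secondary_target_value",
    "secondary_bracket",
    "outer_max",
}


def scenario_config_from_dict(scenario: str, options: Mapping | None = None) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from plain config keys.

    Starts from the scenario's reference config and overrides any key
    provided in ``options`` (coefficient lists are taken on the log scale).
    Unknown keys raise :class:`SpecificationError`.
    """
    options = dict(options or {})
    unknown = set(options) - _CONFIG_KEYS
    if unknown:
        raise SpecificationError(f"unknown config keys: {sorted(unknown)}")
    scenario_key = str(options.pop("target", scenario))
    base_key = scenario_key if scenario_key in ("treatment_prevalence",) else scenario
    population_size = int(options.pop("population_size", 1_000_000))
    seed = int(options.pop("seed", 0))
    configs = default_paper_configs(population_size=population_size, seed=seed)
    if base_key not in configs:
        raise SpecificationError(f"scenario: must be one of {sorted(configs)}, got {base_key!r}")
    config = configs[base_key]

    if {"n_continuous", "n_binary", "binary_p"} & set(options):
        config.covariates = CovariateSpec(
            int(options.pop("n_continuous", config.covariates.n_continuous)),
            int(options.pop("n_binary", config.covariates.n_binary)),
            float(options.pop("binary_p", config.covariates.binary_p)),
            population_size,
        )
    if "target_value" in options:
        config.target_value = float(options.pop("target_value"))
    if "bracket" in options:
        config.bracket = Bracket(*[float(v) for v in options.pop("bracket")])
    tolerance = options.pop("tolerance", None)
    max_iterations = options.pop("max_iterations", None)
    if tolerance is not None or max_iterations is not None:
        config.settings = dataclasses.replace(
            config.settings,
            summary_tolerance=float(tolerance) if tolerance is not None else config.settings.summary_tolerance,
            max_iterations=int(max_iterations) if max_iterations is not None else config.settings.max_iterations,
        )

    if config.scenario == "marginal_hazard_ratio":
        model = config.outcome_model
        config.outcome_model = SurvivalModelSpec(
            coefficients=options.pop("outcome_coefficients", model.coefficients),
            baseline_family=str(options.pop("baseline_family", model.baseline_family)),
            rate=float(options.pop("baseline_rate", model.rate)),
            shape=float(options.pop("baseline_shape", model.shape)),
        )
    else:
        model = config.outcome_model
        config.outcome_model = LogisticModelSpec(
            intercept=float(options.pop("outcome_intercept", model.intercept)),
            coefficients=options.pop("outcome_coefficients", model.coefficients),
            scale=float(options.pop("outcome_scale", model.scale)),
        )
    if config.treatment_model is not None or "treatment_coefficients" in options:
        base = config.treatment_model or LogisticModelSpec(
            intercept=DEFAULT_TREATMENT_INTERCEPT, coefficients=TREATMENT_LOG_ODDS_RATIOS
        )
        config.treatment_model = LogisticModelSpec(
            intercept=float(options.pop("treatment_intercept", base.intercept)),
            coefficients=options.pop("treatment_coefficients", base.coefficients),
        )
    for flag in ("shared_uniforms", "common_random_numbers", "score_with_true_model"):
        if flag in options:
            setattr(config, flag, bool(options.pop(flag)))
    if "secondary_target_value" in options:
        config.secondary_target_value = float(options.pop("secondary_target_value"))
    if "secondary_bracket" in options:
        config.secondary_bracket = Bracket(*[float(v) for v in options.pop("secondary_bracket")])
    if "outer_max" in options:
        config.outer_max = int(options.pop("outer_max"))
    options.pop("baseline_family", None), options.pop("baseline_rate", None), options.pop("baseline_shape", None)
    config.validate()
    return config
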