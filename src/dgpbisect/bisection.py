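"""Stochastic bisection engine for calibrating data-generating processes.

A Monte Carlo data-generating process (DGP) usually exposes one scalar
parameter per data characteristic an investigator wants to control: a
logistic intercept for outcome prevalence, a treatment log-odds ratio for a
marginal relative risk, a coefficient scale for a model c-statistic, a
conditional log-hazard ratio for a marginal hazard ratio.  None of these
maps to its characteristic in closed form, but each map is monotone in
expectation.  The engine here repeatedly halves a bracketing interval on the
parameter, re-simulating the characteristic at every midpoint, until the
simulated summary is as close to the target as desired.

Evaluators are callables ``evaluator(parameter, rng) -> summary`` where
``rng`` is a :class:`numpy.random.Generator` supplied by the engine so that
every evaluation draws from an independent, deterministically derived
substream (or, optionally, from a single common substream so the evaluator
becomes a deterministic monotone function of the parameter).
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import math
from collections.abc import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BracketError, EvaluationError, RangeError, SpecificationError

__all__ = [
    "Bracket",
    "Direction",
    "Decision",
    "BisectionSettings",
    "IterationRecord",
    "CalibrationResult",
    "BisectionProblem",
    "SequentialCalibrationResult",
    "SeedPolicy",
    "bisect_calibrate",
    "find_bracket",
    "sequential_calibrate",
    "write_trace",
    "read_trace",
    "TRACE_COLUMNS",
]

Evaluator = Callable[[float, np.random.Generator], float]

TRACE_COLUMNS = ("iteration", "lower", "upper", "midpoint", "summary", "target", "decision")


class Direction(str, enum.Enum):
    """Expected monotonicity of the evaluator in the calibrated parameter."""

    INCREASING = "increasing"
    DECREASING = "decreasing"


class Decision(str, enum.Enum):
    """Which half of the bracket was kept after an iteration."""

    GO_UP = "go_up"
    GO_DOWN = "go_down"
    STOP = "stop"


@dataclasses.dataclass(frozen=True)
class Bracket:
    """A finite open interval (lower, upper) on the parameter axis."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise SpecificationError("bracket endpoints must be finite")
        if not self.lower < self.upper:
            raise SpecificationError(
                f"bracket lower endpoint must be below upper endpoint, got ({self.lower}, {self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclasses.dataclass(frozen=True)
class BisectionSettings:
    """Stopping rule and orientation for one calibration.

    The search stops at the first iteration whose summary lies within
    ``summary_tolerance`` of the target, or after ``max_iterations``,
    whichever comes first.  ``summary_tolerance`` is expressed in the
    summary's own units (a proportion, a relative risk, ...).
    """

    max_iterations: int = 25
    summary_tolerance: float = 0.0
    direction: Direction = Direction.INCREASING
    check_bracket: bool = True

    def __post_init__(self) -> None:
        if int(self.max_iterations) < 1:
            raise SpecificationError("max_iterations must be >= 1")
        if self.summary_tolerance < 0:
            raise SpecificationError("summary_tolerance must be >= 0")
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))


@dataclasses.dataclass(frozen=True)
class IterationRecord:
    """One row of the calibration trace."""

    iteration: int
    bracket_before: Bracket
    midpoint: float
    summary: float
    decision: Decision
    bracket_after: Bracket


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a bisection calibration, with its full iteration trace."""

    final_parameter: float
    final_summary: float
    target: float
    converged: bool
    trace: tuple[IterationRecord, ...]
    seed: int | None = None

    def trace_frame(self) -> pd.DataFrame:
        """Return the trace as a DataFrame with the canonical trace columns."""
        rows = [
            (
                r.iteration,
                r.bracket_before.lower,
                r.bracket_before.upper,
                r.midpoint,
                r.summary,
                self.target,
                r.decision.value,
            )
            for r in self.trace
        ]
        return pd.DataFrame(rows, columns=list(TRACE_COLUMNS))


class SeedPolicy:
    """Deterministic derivation of per-evaluation random substreams.

    Substream ``index`` maps to ``default_rng(SeedSequence((base_seed, index)))``
    so that evaluations are mutually independent yet fully reproducible from
    one base seed.  With ``common_random_numbers=True`` every index collapses
    to substream 0: each evaluation then sees identical random draws, which
    turns an empirical evaluator into a deterministic monotone function of
    the parameter and removes decision-flip risk near convergence.
    """

    def __init__(self, base_seed: int = 0, common_random_numbers: bool = False):
        base_seed = int(base_seed)
        if base_seed < 0:
            raise SpecificationError("base_seed must be a nonnegative integer")
        self.base_seed = base_seed
        self.common_random_numbers = bool(common_random_numbers)

    def rng(self, index: int) -> np.random.Generator:
        if self.common_random_numbers:
            index = 0
        return np.random.default_rng(np.random.SeedSequence((self.base_seed, int(index))))

    def child(self, *key: int) -> "SeedPolicy":
        """Derive an independent policy for a nested calibration (sweep, slot)."""
        state = np.random.SeedSequence((self.base_seed, *[int(k) for k in key])).generate_state(1)[0]
        return SeedPolicy(int(state), self.common_random_numbers)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SeedPolicy(base_seed={self.base_seed}, common_random_numbers={self.common_random_numbers})"


def _coerce_policy(seed_policy: SeedPolicy | int | None) -> SeedPolicy:
    if seed_policy is None:
        return SeedPolicy(0)
    if isinstance(seed_policy, SeedPolicy):
        return seed_policy
    return SeedPolicy(int(seed_policy))


def _evaluate(evaluator: Evaluator, parameter: float, rng: np.random.Generator) -> float:
    summary = float(evaluator(parameter, rng))
    if not math.isfinite(summary):
        raise EvaluationError(f"evaluator returned non-finite summary {summary!r} at parameter {parameter!r}")
    return summary


def bisect_calibrate(
    evaluator: Evaluator,
    target: float,
    bracket: Bracket,
    settings: BisectionSettings | None = None,
    seed_policy: SeedPolicy | int | None = None,
) -> CalibrationResult:
    """Calibrate a scalar parameter so the evaluator's summary hits ``target``.

    Parameters
    ----------
    evaluator
        ``(parameter, rng) -> summary``; monotone in expectation with the
        orientation declared in ``settings.direction``.
    target
        Desired summary value, in the summary's units.
    bracket
        Initial interval whose endpoint summaries straddle the target.
        Endpoint straddling is verified with one evaluation per endpoint
        unless ``settings.check_bracket`` is False (each check costs a full
        simulation of the super-population outcomes).
    settings
        Stopping rule; defaults to 25 iterations with zero tolerance.
    seed_policy
        A :class:`SeedPolicy` or base-seed integer driving the per-evaluation
        substreams.

    Returns
    -------
    CalibrationResult
        The last midpoint as ``final_parameter``, the summary simulated at
        it, a convergence flag, and the full iteration trace.
    """
    settings = BisectionSettings() if settings is None else settings
    policy = _coerce_policy(seed_policy)
    if not isinstance(bracket, Bracket):
        bracket = Bracket(*bracket)
    sign = 1.0 if settings.direction is Direction.INCREASING else -1.0

    lo, hi = bracket.lower, bracket.upper
    if settings.check_bracket:
        s_lo = _evaluate(evaluator, lo, policy.rng(settings.max_iterations + 1))
        s_hi = _evaluate(evaluator, hi, policy.rng(settings.max_iterations + 2))
        if not (sign * (s_lo - target) < 0.0 < sign * (s_hi - target)):
            raise BracketError(
                f"bracket ({lo}, {hi}) does not straddle target {target} for a "
                f"{settings.direction.value} evaluator: summary(lower)={s_lo}, summary(upper)={s_hi}"
            )

    trace: list[IterationRecord] = []
    midpoint = summary = math.nan
    converged = False
    for iteration in range(1, settings.max_iterations + 1):
        before = Bracket(lo, hi)
        midpoint = 0.5 * (lo + hi)
        summary = _evaluate(evaluator, midpoint, policy.rng(iteration))
        error = summary - target
        converged = abs(error) <= settings.summary_tolerance
        # Keep the upper half when the (direction-adjusted) summary falls short
        # of the target; an exact tie stops and keeps the upper half by convention.
        keep_upper = sign * error <= 0.0
        after = Bracket(midpoint, hi) if keep_upper else Bracket(lo, midpoint)
        decision = Decision.STOP if converged else (Decision.GO_UP if keep_upper else Decision.GO_DOWN)
        trace.append(IterationRecord(iteration, before, midpoint, summary, decision, after))
        lo, hi = after.lower, after.upper
        if converged:
            break

    return CalibrationResult(
        final_parameter=midpoint,
        final_summary=summary,
        target=target,
        converged=converged,
        trace=tuple(trace),
        seed=policy.base_seed,
    )


def find_bracket(
    evaluator: Evaluator,
    target: float,
    center: float,
    initial_halfwidth: float,
    direction: Direction = Direction.INCREASING,
    max_doublings: int = 10,
    seed_policy: SeedPolicy | int | None = None,
) -> Bracket:
    """Find a straddling bracket by symmetric geometric expansion around ``center``.

    The interval ``(center - h, center + h)`` is evaluated with ``h`` starting
    at ``initial_halfwidth`` and doubling after each failed attempt, up to
    ``max_doublings`` doublings.  Failure to straddle within the budget raises
    :class:`RangeError`, signalling a target outside the evaluator's achievable
    range (e.g. a prevalence target outside (0, 1)).
    """
    if not initial_halfwidth > 0:
        raise SpecificationError("initial_halfwidth must be > 0")
    if int(max_doublings) < 1:
        raise SpecificationError("max_doublings must be >= 1")
    direction = Direction(direction)
    sign = 1.0 if direction is Direction.INCREASING else -1.0
    policy = _coerce_policy(seed_policy)

    halfwidth = float(initial_halfwidth)
    for attempt in range(int(max_doublings) + 1):
        lo, hi = center - halfwidth, center + halfwidth
        s_lo = _evaluate(evaluator, lo, policy.rng(2 * attempt + 1))
        s_hi = _evaluate(evaluator, hi, policy.rng(2 * attempt + 2))
        if sign * (s_lo - target) < 0.0 < sign * (s_hi - target):
            return Bracket(lo, hi)
        halfwidth *= 2.0
    raise RangeError(
        f"no bracket straddling target {target} found around {center} within "
        f"{max_doublings} doublings of halfwidth {initial_halfwidth}; "
        "the target may lie outside the evaluator's achievable range"
    )


# ---------------------------------------------------------------------------
# Sequential (coordinate-wise) calibration of several characteristics
# ---------------------------------------------------------------------------

JointEvaluator = Callable[[float, Mapping[str, float], np.random.Generator], float]


@dataclasses.dataclass(frozen=True)
class BisectionProblem:
    """One parameter/characteristic pair within a sequential calibration.

    ``evaluator(parameter, frozen, rng)`` receives the current values of all
    *other* problems' parameters in ``frozen`` (keyed by problem name), so the
    problems can share one data-generating process.  ``initial`` is the value
    this parameter is frozen at before its first calibration; defaults to the
    bracket midpoint.
    """

    name: str
    evaluator: JointEvaluator
    target: float
    bracket: Bracket
    settings: BisectionSettings
    initial: float | None = None


@dataclasses.dataclass(frozen=True)
class SequentialCalibrationResult:
    names: tuple[str, ...]
    results: tuple[CalibrationResult, ...]
    converged: bool
    sweeps: int

    def as_dict(self) -> dict[str, CalibrationResult]:
        return dict(zip(self.names, self.results))

    @property
    def parameters(self) -> dict[str, float]:
        return {n: r.final_parameter for n, r in zip(self.names, self.results)}


def sequential_calibrate(
    problems: Sequence[BisectionProblem],
    outer_max: int = 5,
    joint_tolerances: Sequence[float] | None = None,
    seed_policy: SeedPolicy | int | None = None,
) -> SequentialCalibrationResult:
    """Calibrate several characteristics of one DGP by cyclic bisection.

    Each sweep re-runs :func:`bisect_calibrate` for every problem in turn with
    the other parameters frozen at their current values, then re-simulates all
    summaries jointly.  Sweeps repeat until every summary is simultaneously
    within its tolerance (``joint_tolerances``, defaulting to each problem's
    ``summary_tolerance``) or ``outer_max`` sweeps elapse.  Re-sweeping is
    needed because calibrating one characteristic generally perturbs the
    others (e.g. rescaling coefficients for a c-statistic shifts prevalence).
    """
    problems = list(problems)
    if len(problems) == 0:
        raise SpecificationError("at least one problem is required")
    names = [p.name for p in problems]
    if len(set(names)) != len(names):
        raise SpecificationError(f"problem names must be distinct, got {names}")
    if int(outer_max) < 1:
        raise SpecificationError("outer_max must be >= 1")
    tolerances = (
        [p.settings.summary_tolerance for p in problems]
        if joint_tolerances is None
        else [float(t) for t in joint_tolerances]
    )
    if len(tolerances) != len(problems):
        raise SpecificationError("joint_tolerances must match the number of problems")

    policy = _coerce_policy(seed_policy)
    current = {p.name: (p.bracket.midpoint if p.initial is None else float(p.initial)) for p in problems}
    results: dict[str, CalibrationResult] = {}
    converged = False
    sweeps = 0
    for sweep in range(1, int(outer_max) + 1):
        sweeps = sweep
        for j, problem in enumerate(problems):
            frozen = {k: v for k, v in current.items() if k != problem.name}

            def frozen_evaluator(x: float, rng: np.random.Generator, _p=problem, _f=frozen) -> float:
                return _p.evaluator(x, _f, rng)

            try:
                result = bisect_calibrate(
                    frozen_evaluator,
                    problem.target,
                    problem.bracket,
                    problem.settings,
                    policy.child(sweep, j),
                )
            except (BracketError, RangeError, EvaluationError) as exc:
                raise type(exc)(f"sweep {sweep}, problem {problem.name!r}: {exc}") from exc
            current[problem.name] = result.final_parameter
            results[problem.name] = result

        joint_ok = True
        for j, (problem, tolerance) in enumerate(zip(problems, tolerances)):
            frozen = {k: v for k, v in current.items() if k != problem.name}
            rng = policy.child(sweep, len(problems) + j).rng(0)
            summary = float(problem.evaluator(current[problem.name], frozen, rng))
            if not abs(summary - problem.target) <= tolerance:
                joint_ok = False
                break
        if joint_ok:
            converged = True
            break

    return SequentialCalibrationResult(
        names=tuple(names),
        results=tuple(results[n] for n in names),
        converged=converged,
        sweeps=sweeps,
    )


# ---------------------------------------------------------------------------
# Trace persistence
# ---------------------------------------------------------------------------


def write_trace(result: CalibrationResult, path) -> None:
    """Write a calibration trace as delimited text, one row per iteration.

    Floats are written with ``repr`` so the file round-trips bit-exactly.
    ``lower``/``upper`` are the pre-iteration bracket endpoints; together with
    the decision column they determine every subsequent bracket.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRACE_COLUMNS)
        for r in result.trace:
            writer.writerow(
                [
                    r.iteration,
                    repr(r.bracket_before.lower),
                    repr(r.bracket_before.upper),
                    repr(r.midpoint),
                    repr(r.summary),
                    repr(result.target),
                    r.decision.value,
                ]
            )


def read_trace(path, direction: Direction = Direction.INCREASING) -> CalibrationResult:
    """Reconstruct a :class:`CalibrationResult` from a trace file.

    ``direction`` is needed only to rebuild the half-bracket recorded on a
    STOP row (the trace format carries no direction column); it defaults to
    the increasing orientation used by all built-in scenarios.
    """
    direction = Direction(direction)
    sign = 1.0 if direction is Direction.INCREASING else -1.0
    records: list[IterationRecord] = []
    target = math.nan
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != TRACE_COLUMNS:
            raise SpecificationError(f"unexpected trace header {header!r}")
        for row in reader:
            iteration = int(row[0])
            lower, upper, midpoint, summary, target = (float(v) for v in row[1:6])
            decision = Decision(row[6])
            before = Bracket(lower, upper)
            if decision is Decision.GO_UP:
                keep_upper = True
            elif decision is Decision.GO_DOWN:
                keep_upper = False
            else:
                keep_upper = sign * (summary - target) <= 0.0
            after = Bracket(midpoint, upper) if keep_upper else Bracket(lower, midpoint)
            records.append(IterationRecord(iteration, before, midpoint, summary, decision, after))
    if not records:
        raise SpecificationError(f"trace file {path!r} contains no iterations")
    last = records[-1]
    return CalibrationResult(
        final_parameter=last.midpoint,
        final_summary=last.summary,
        target=target,
        converged=last.decision is Decision.STOP,
        trace=tuple(records),
        seed=None,
    )
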