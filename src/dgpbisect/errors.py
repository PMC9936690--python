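"""Exception hierarchy shared across the package."""


class SpecificationError(ValueError):
    """An input object violates its declared invariants (shapes, ranges, roles)."""


class BracketError(ValueError):
    """The supplied bracket endpoints do not straddle the target summary."""


class RangeError(ValueError):
    """No straddling bracket could be found; the target is likely unattainable."""


class EvaluationError(ValueError):
    """A stochastic evaluator returned a non-finite summary."""


class FitError(RuntimeError):
    """A likelihood fit failed (single-class outcome, separation, divergence)."""


class ConvergenceError(FitError):
    """An iterative maximizer did not converge (e.g. monotone partial likelihood)."""


class DegenerateEstimandError(ValueError):
    """A marginal estimand is undefined (e.g. zero control-arm risk)."""
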