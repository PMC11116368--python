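"""Exception hierarchy for comgem."""


class ComgemError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ComgemError):
    """A model file could not be parsed; names the offending element."""


class ValidationError(ComgemError):
    """A model violates structural invariants.

    Carries the full list of violations so callers can report them all.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("model validation failed:\n  " + "\n  ".join(self.violations))


class FormulaError(ComgemError):
    """A chemical formula string could not be interpreted."""


class NamespaceConflictError(ComgemError):
    """Reference table maps one source id to several common ids."""

    def __init__(self, conflicts):
        self.conflicts = list(conflicts)
        super().__init__(
            "conflicting namespace rows:\n  "
            + "\n  ".join(f"{s} -> {sorted(t)}" for s, t in self.conflicts)
        )


class FluxError(ComgemError):
    """Base class for constraint-based solver failures."""


class InfeasibleError(FluxError):
    """The LP/MILP has no feasible solution."""


class UnboundedError(FluxError):
    """The LP objective is unbounded."""


class GapfillInfeasibleError(InfeasibleError):
    """Gap-filling cannot reach the growth threshold even with the full database.

    ``blocked_precursors`` lists biomass substrates that cannot be synthesised
    at the required rate (found by per-precursor demand relaxation).
    """

    def __init__(self, model_id, blocked_precursors):
        self.model_id = model_id
        self.blocked_precursors = sorted(blocked_precursors)
        super().__init__(
            f"gap-filling infeasible for {model_id}; "
            f"blocked biomass precursors: {self.blocked_precursors}"
        )


class UndefinedStatisticError(ComgemError):
    """A statistic (e.g. Pearson r on a constant vector) is undefined."""
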