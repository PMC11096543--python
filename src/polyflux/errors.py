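"""Exception hierarchy shared across the pipeline.

Exit codes used by the CLI: 2 validation, 3 infeasibility, 4 solver failure.
"""


class PolyfluxError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(PolyfluxError):
    """Input violates a documented invariant. Carries all violations found."""

    exit_code = 2

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class FormatError(PolyfluxError):
    """A file failed to parse in its declared format."""

    exit_code = 2


class InfeasibleError(PolyfluxError):
    """A constraint set admits no flux vector.

    ``detail`` may carry diagnostics such as the smallest window scaling
    that restores feasibility, or an irreducible constraint subset.
    """

    exit_code = 3

    def __init__(self, message, detail=None):
        super().__init__(message)
        self.detail = detail


class DegenerateInputError(PolyfluxError):
    """An operation received input that makes its result undefined (e.g. zero AUC)."""

    exit_code = 2


class SolverError(PolyfluxError):
    """The LP solver failed for reasons other than infeasibility."""

    exit_code = 4
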