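"""Exception hierarchy for netgs."""


class NetgsError(Exception):
    """Base class for all package errors."""


class FormatError(NetgsError):
    """A file could not be parsed in the requested dialect."""


class ValidationError(NetgsError):
    """An object violates a structural invariant or precondition."""


class InfeasibleError(NetgsError):
    """An optimization program has an empty feasible region."""

    def __init__(self, message, constraint_group=None):
        super().__init__(message)
        self.constraint_group = constraint_group


class UnboundedError(NetgsError):
    """A linear program is unbounded; usually a missing exchange bound."""


class SolverError(NetgsError):
    """The numerical solver failed to converge."""

    def __init__(self, message, status=None):
        super().__init__(message)
        self.status = status


class DegenerateInputError(NetgsError):
    """A statistic was requested on degenerate input (e.g. zero variance)."""
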