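"""Exception types shared across the toolkit."""


class DSError(Exception):
    """Base class for all toolkit errors."""


class ModelSyntaxError(DSError):
    """An equation string could not be tokenized or parsed.

    Carries the character position of the offending token so callers can
    point at the problem in the source line.
    """

    def __init__(self, message, text=None, position=None):
        self.text = text
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ModelStructureError(DSError):
    """The parsed equations violate a structural requirement of the GMA form
    (missing auxiliary constraint, equation without positive/negative terms, ...).
    """


class UnsupportedFormError(DSError):
    """A rational-rate-law model contains a construct that cannot be recast
    (e.g. a denominator that is not a sum of power laws)."""


class VariableDomainError(DSError):
    """A variable or parameter is missing or assigned a non-positive value."""


class NoSolutionError(DSError):
    """A requested parameter set does not exist (infeasible polytope).

    ``certificate`` holds the LP status message returned by the solver.
    """

    def __init__(self, message, certificate=None):
        self.certificate = certificate
        super().__init__(message)


class SingularSystemError(DSError):
    """A dominant S-system is underdetermined (singular log-linear block)."""


class RouthDegenerateError(DSError):
    """The Routh array has a zero pivot; fall back to eigenvalue counting."""
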