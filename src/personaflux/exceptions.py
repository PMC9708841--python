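"""Exception hierarchy."""


class PersonaFluxError(Exception):
    """Base class for all package errors."""


class ModelFormatError(PersonaFluxError):
    """A model file could not be parsed; the message names the offending element."""


class ValidationError(PersonaFluxError):
    """A network or input table violates a structural invariant."""


class InfeasibleError(PersonaFluxError):
    """An optimisation problem has no feasible point (or is unbounded)."""

    def __init__(self, message: str, status: str | None = None):
        super().__init__(message if status is None else f"{message} (solver status: {status})")
        self.status = status


class SolverError(PersonaFluxError):
    """The numerical solver failed to converge."""
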