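"""Exception types shared across the package."""


class IfnSynergyError(Exception):
    """Base class for package errors."""


class ParseError(IfnSynergyError, ValueError):
    """A file or pattern could not be parsed."""


class ValidationError(IfnSynergyError, ValueError):
    """Inputs violate a documented precondition or invariant."""


class GenerationError(IfnSynergyError, RuntimeError):
    """The synthetic-data generator could not satisfy its constraints."""


class PipelineError(IfnSynergyError, RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""
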