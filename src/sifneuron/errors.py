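"""Exception hierarchy shared across the package."""


class SifneuronError(Exception):
    """Base class for all package errors."""


class MappingError(SifneuronError):
    """A spike train references an input source with no conductance group."""


class StateCorruptionError(SifneuronError):
    """A conductance state violated its invariants (e.g. negative value)."""


class ResolutionError(SifneuronError):
    """The integration step is too coarse for the synaptic kinetics."""


class EmptyHorizonError(SifneuronError):
    """A simulation was requested over a zero-length horizon."""


class DomainError(SifneuronError):
    """A constructor argument lies outside its mathematical domain."""


class CapabilityError(SifneuronError):
    """A method was asked to handle a problem size it does not support."""


class TableParseError(SifneuronError):
    """A delimited-text input could not be parsed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
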