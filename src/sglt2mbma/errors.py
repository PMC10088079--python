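"""Exception hierarchy shared across the package."""


class MBMAError(Exception):
    """Base class for package errors."""


class InputError(MBMAError, ValueError):
    """Malformed user input (bad time grid, missing labels, empty data)."""


class DomainError(MBMAError, ValueError):
    """Parameter or argument outside its mathematical domain."""


class ConfigurationError(MBMAError, ValueError):
    """A parameter set violates a structural invariant of the model."""


class SchemaError(MBMAError, ValueError):
    """A dataset file does not match its declared schema."""


class NumericError(MBMAError, RuntimeError):
    """An ODE solve or optimization failed irrecoverably."""
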