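"""Exception hierarchy for brainreg.

All readers and pipeline stages raise subclasses of :class:`BrainregError`
so callers can distinguish bad input files, inconsistent data, and invalid
configuration from programming errors.
"""


class BrainregError(Exception):
    """Base class for all brainreg errors."""


class FormatError(BrainregError):
    """A file violates its format contract (names file, line and rule)."""

    def __init__(self, path, line, rule):
        self.path = str(path)
        self.line = line
        self.rule = rule
        super().__init__(f"{self.path}:{line}: {rule}")


class ConsistencyError(BrainregError):
    """Two inputs that must agree do not (e.g. counts vs. metadata)."""


class ConfigurationError(BrainregError):
    """A configuration value is outside its documented domain."""


class InputError(BrainregError):
    """An in-memory argument violates an operation's precondition."""


class EstimationError(BrainregError):
    """A statistical quantity cannot be estimated from the given data."""
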