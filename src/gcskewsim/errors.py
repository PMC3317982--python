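"""Exception hierarchy shared across the package."""


class GcSkewSimError(Exception):
    """Base class for all package errors."""


class FormatError(GcSkewSimError):
    """A file could not be parsed under its declared standard."""


class InputError(GcSkewSimError):
    """Caller-supplied data violates an operation's precondition."""


class ConfigError(GcSkewSimError):
    """A configuration value is invalid or infeasible."""


class ModelConstructionError(GcSkewSimError):
    """A termination model cannot be built from the given annotation."""


class DegenerateSignalError(GcSkewSimError):
    """The skew signal is too flat to locate origin/terminus."""


class SimulationStallError(GcSkewSimError):
    """No eligible position remains for the mutation engine."""
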