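"""Exception hierarchy shared across the package."""


class TcrtmeError(Exception):
    """Base class for all package-specific errors."""


class EmptyRepertoireError(TcrtmeError):
    """A clonotype table with no rows where a nonempty repertoire is required."""


class InvalidConfigurationError(TcrtmeError, ValueError):
    """A parameter outside its declared range or an inconsistent configuration."""


class UndefinedStatisticError(TcrtmeError):
    """A statistic whose value is undefined for the given input (e.g. one-class AUC,
    constant-vector correlation, a core with zero scored cells)."""


class InsufficientDataError(TcrtmeError):
    """Too few observations to run a test (fewer complete pairs / group members
    than the test's minimum)."""


class PairingError(TcrtmeError):
    """Pre/post records that do not share the same pairing key, marker or compartment."""


class FormatError(TcrtmeError):
    """An input file that does not match the expected column schema."""
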