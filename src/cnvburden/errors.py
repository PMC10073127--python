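"""Exception hierarchy shared across the package."""


class CnvBurdenError(Exception):
    """Base class for all package errors."""


class ParseError(CnvBurdenError):
    """A file could not be parsed; the message names the file and line."""


class SchemaError(CnvBurdenError):
    """A tabular input is missing mandatory columns or has illegal values."""


class ValidationError(CnvBurdenError):
    """A domain object violates one of its invariants."""


class ConfigError(CnvBurdenError):
    """A simulation or pipeline configuration is internally inconsistent."""


class UsageError(CnvBurdenError):
    """An operation was called with inputs outside its contract."""


class PipelineError(CnvBurdenError):
    """A pipeline stage failed; the message names the stage."""
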