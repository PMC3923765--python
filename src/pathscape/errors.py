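"""Exception hierarchy used across the package."""


class PathscapeError(Exception):
    """Base class for all package errors."""


class NotFoundError(PathscapeError, KeyError):
    """A component id was not found in the model."""


class FormatError(PathscapeError, ValueError):
    """Malformed input file or unparsable text."""


class ConfigError(PathscapeError, ValueError):
    """Inconsistent configuration (bad scale/target pairing, unknown engine, ...)."""


class ExpressionError(PathscapeError, ValueError):
    """Unparsable or unresolvable sample expression; message names the offending token."""


class SchemaVersionError(FormatError):
    """Project file schema version does not match the reader's."""


class StalenessError(PathscapeError, RuntimeError):
    """A flat-graph result no longer matches the model it was derived from."""


class ParameterError(PathscapeError, ValueError):
    """Infeasible generator or operation parameters."""


class StateError(PathscapeError, RuntimeError):
    """Operation called before its pipeline prerequisites ran."""
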