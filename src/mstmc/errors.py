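"""Exception hierarchy shared across the package."""


class MstmcError(Exception):
    """Base class of all package-specific errors."""


class FormatError(MstmcError):
    """Malformed input document (XML/CSV) or non-numeric value text."""


class StructureError(MstmcError):
    """Architecture graph is not a rooted tree."""


class GraphLookupError(MstmcError):
    """A scale.subsystem vertex is not present in the architecture graph."""


class TraceOrderError(MstmcError):
    """Timepoint timestamps are not strictly increasing."""


class RangeError(MstmcError):
    """A value lies outside its declared valid range."""


class BindingError(MstmcError):
    """A symbol in a specification does not resolve against graph/registry."""


class ParseError(MstmcError):
    """Specification text is syntactically invalid."""

    def __init__(self, message, line=None, column=None):
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)
        self.line = line
        self.column = column


class HorizonError(MstmcError):
    """Trace too short to evaluate all bounded temporal operators."""


class NumericError(MstmcError):
    """Arithmetic failure during formula evaluation (div by zero, ...)."""


class EvaluationError(MstmcError):
    """Generic evaluation failure (missing variable, ...)."""


class RegistryError(MstmcError):
    """Unknown spatial entity type or measure."""


class ConfigError(MstmcError):
    """Invalid spatial configuration document."""


class SampleError(MstmcError):
    """Outcome provider exhausted before the checker could decide."""


class ParameterError(MstmcError):
    """Checker parameter outside its admissible range."""


class GenerationError(MstmcError):
    """External trace generator misbehaved (timeout, no file produced)."""


class PathError(MstmcError):
    """A state sequence is not a path of the transition system."""


class ShapeSpecError(MstmcError):
    """Overlapping or out-of-bounds shapes in a synthetic grid request."""
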