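"""Exception types shared across the pipeline."""


class IrclustError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IrclustError):
    """A file is structurally wrong (e.g. a mandatory column is missing)."""


class ParseError(IrclustError):
    """A cell could not be parsed; message carries the position."""


class DomainError(IrclustError, ValueError):
    """A value violates a mathematical precondition (e.g. log of age 0)."""


class ConsistencyError(IrclustError):
    """Two objects that must align (ids, shapes) do not."""


class ParameterError(IrclustError, ValueError):
    """An argument is outside its allowed range."""


class DegenerateLabelsError(IrclustError):
    """A label vector has a single class where two are required."""
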