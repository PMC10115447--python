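"""Exception types shared across the package."""


class XCompareError(Exception):
    """Base class for all package errors."""


class FormatError(XCompareError):
    """A file or table does not conform to the expected schema."""


class EmptyInputError(XCompareError):
    """An input file or repertoire contained no usable records."""


class EmptyResultError(XCompareError):
    """An operation produced an empty result (e.g. a filter removed everything)."""


class ParseError(XCompareError):
    """A gene-call string could not be parsed."""


class AnnotationError(XCompareError):
    """A record lacks the annotation needed for the requested computation."""


class SimulationError(XCompareError):
    """The simulator could not satisfy its constraints within budget."""
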