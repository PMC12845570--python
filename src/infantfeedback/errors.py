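"""Exception hierarchy shared across the package.

Input/format problems (:class:`SchemaError`, :class:`ParseError`,
:class:`EmptyInputError`) map to CLI exit code 2; violated analysis
preconditions (:class:`AnalysisError`) map to exit code 3.
"""


class InfantFeedbackError(Exception):
    """Base class for all package errors."""


class SchemaError(InfantFeedbackError):
    """Input file does not match the documented schema (columns, keys, ids)."""


class ParseError(InfantFeedbackError):
    """A row or line could not be parsed; message names the offending location."""


class EmptyInputError(InfantFeedbackError):
    """An input that must contain data is empty."""


class AnalysisError(InfantFeedbackError):
    """A precondition of an analysis operation is not met."""
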