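"""Exception hierarchy.

Validation-type errors (bad inputs, malformed files) map to CLI exit code 2,
everything else raised at run time maps to exit code 3.
"""


class GaitRiskError(Exception):
    """Base class for all package errors."""


class FormatError(GaitRiskError, ValueError):
    """A file does not conform to the expected dialect (header, columns)."""


class ValidationError(GaitRiskError, ValueError):
    """Input data violates a documented invariant."""


class ParameterError(GaitRiskError, ValueError):
    """A parameter is outside its documented range."""


class InsufficientDataError(GaitRiskError, ValueError):
    """Too few samples/steps/events for the requested operation."""
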