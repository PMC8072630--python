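"""Exception hierarchy.

All package-raised errors derive from :class:`MetskipError` so callers can
distinguish data/usage problems from programming errors.
"""


class MetskipError(Exception):
    """Base class for all errors raised by metskip."""


class AnnotationNotFoundError(MetskipError):
    """Requested gene/transcript is absent from the annotation."""


class CoordinateError(MetskipError):
    """A genomic coordinate falls outside the available sequence."""


class DataError(MetskipError):
    """Input data violates a precondition (wrong shape, empty, degenerate)."""


class SchemaMismatchError(MetskipError):
    """Feature schema hash does not match the one a model was trained on."""
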