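"""Exception hierarchy.

All user-facing failures derive from :class:`SegffError` so the CLI can map
them onto exit codes without ever surfacing a traceback.
"""


class SegffError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(SegffError):
    """A segmentation (or an edit to one) violates a model invariant."""

    def __init__(self, message, violations=None):
        super().__init__(message)
        self.violations = list(violations or [])


class FormatError(SegffError):
    """A file could not be parsed or written in the requested encoding."""


class VersionError(FormatError):
    """The file declares a schema version newer than this library supports."""


class TransformError(SegffError):
    """Affine-transform algebra failure (e.g. non-invertible matrix)."""
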