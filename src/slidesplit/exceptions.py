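"""Exception hierarchy shared across the toolkit.

``SlideOpenError`` is deliberately distinct from the generic
``ValidationError``: the archiving workflow routes slides that fail to open
into its failure folder, so callers must be able to tell "this file is not a
readable slide" apart from "this request was malformed".
"""


class SlideSplitError(Exception):
    """Base class for all toolkit errors."""


class SlideOpenError(SlideSplitError):
    """A slide file could not be opened (missing, corrupt, or unregistered format)."""


class BoundsError(SlideSplitError):
    """A region request falls outside the slide, or addresses an invalid tile."""


class UnsupportedMagnificationError(SlideSplitError):
    """A region was requested above the scan magnification (upsampling)."""


class ValidationError(SlideSplitError):
    """An argument violates a documented precondition."""


class StoreError(SlideSplitError):
    """The specimen record store is unreachable or failed mid-operation (retryable)."""
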