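"""Exception hierarchy for xtc reading, writing and decoding."""


class XtcError(Exception):
    """Base class for all errors raised by this package."""


class XtcFormatError(XtcError):
    """The byte stream is not a well-formed xtc frame (bad magic, bad field)."""

    def __init__(self, message: str, *, offset: int | None = None, value=None):
        super().__init__(message)
        self.offset = offset
        self.value = value


class XtcTruncationError(XtcError):
    """End of file reached inside a frame (mid-write kill, copy error...)."""

    def __init__(self, message: str, *, offset: int | None = None, frame: int | None = None):
        super().__init__(message)
        self.offset = offset
        self.frame = frame


class XtcRangeError(XtcError, ValueError):
    """A value is outside the range the codec or format can represent."""


class XtcCorruptionError(XtcError):
    """A compressed payload decodes inconsistently (wrong atom count, bad state)."""


class IndexCorruptionError(XtcCorruptionError):
    """Mid-file corruption hit while indexing; carries the salvage offset."""

    def __init__(self, message: str, *, last_good_offset: int, partial_index=None):
        super().__init__(message)
        self.last_good_offset = last_good_offset
        self.partial_index = partial_index


class BitstreamUnderrun(XtcError):
    """Fewer bits remain in a buffer than a read or skip requested."""


class MonotonicityError(XtcError):
    """Frame times are not monotonically non-decreasing; time search refused."""


class PastEndError(XtcError, LookupError):
    """A time query lies beyond the last frame of the trajectory."""
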