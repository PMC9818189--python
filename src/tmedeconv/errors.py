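"""Exception hierarchy.

All package errors derive from :class:`TMEDeconvError` so callers (and the
CLI) can catch one type and report a clean one-line diagnostic.
"""


class TMEDeconvError(Exception):
    """Base class for every error raised by this package."""


class ConfigurationError(TMEDeconvError):
    """An invalid parameter, spec, or argument combination."""


class DataError(TMEDeconvError):
    """Input data violate a precondition (shape, sign, labels, coverage)."""


class FileFormatError(TMEDeconvError):
    """A file on disk does not follow the expected dialect."""
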