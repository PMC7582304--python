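"""Exception hierarchy.

Errors are split by where the problem lies: the file format, the data
content, the channel metadata, or the parameters of an operation, so that
a pipeline can report failures precisely.
"""


class CryoleafError(Exception):
    """Base class for all package errors."""


class FormatError(CryoleafError):
    """A file does not have the expected layout (e.g. missing timestamp column)."""


class DataError(CryoleafError):
    """The data violate an invariant (non-monotone timestamps, empty table, ...)."""


class MetadataError(CryoleafError):
    """Channel metadata are missing or inconsistent with the data columns."""


class ParameterError(CryoleafError):
    """An operation was called with invalid parameters."""


class GeometryError(CryoleafError):
    """A cell outline is not a valid simple polygon."""
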