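"""Exception hierarchy shared by all pipeline stages."""


class CnpError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(CnpError):
    """A table violates its documented column schema or key constraints."""


class UnitError(CnpError):
    """An unknown or inconsistent unit label was supplied."""


class MissingDataError(CnpError):
    """A required value is absent (and the operation cannot flag-and-continue)."""


class InconsistentDataError(CnpError):
    """Upstream tables contradict each other (e.g. consumption without area)."""


class GridMismatchError(CnpError):
    """Two rasters do not share shape, transform, or CRS."""
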