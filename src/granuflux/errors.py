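"""Exception hierarchy for granuflux."""


class GranufluxError(Exception):
    """Base class for all granuflux errors."""


class FormatError(GranufluxError):
    """A file or table does not conform to the expected dialect."""


class ValidationError(GranufluxError):
    """Data violate a structural invariant (ordering, uniqueness, ranges)."""


class ConfigurationError(GranufluxError):
    """An analysis was requested with an inconsistent or incomplete setup,
    e.g. a schedule missing a required injection event."""


class CalibrationError(GranufluxError):
    """Oxygen calibration could not be established from the reference wells."""
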