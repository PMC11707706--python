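"""Exception hierarchy for input validation and pipeline contracts.

Readers reject rather than coerce: every malformed row raises a distinct,
named error that identifies the offending row(s) and value(s).
"""


class ValidationError(ValueError):
    """Base class for malformed interchange-table content."""


class MissingColumnError(ValidationError):
    """A required header column is absent."""


class DuplicateIdError(ValidationError):
    """A centroid_id occurs more than once in a table that requires uniqueness."""


class UnknownRoleError(ValidationError):
    """A centroid role outside {garden, reference, village_center}."""


class CoordinateError(ValidationError):
    """A coordinate that is non-numeric or non-finite."""


class GeographicCoordinateError(ValidationError):
    """Coordinates that look like geographic lon/lat rather than projected meters.

    The 1 km village radius and nearest-reference pairing are Euclidean, so
    inputs must be in a projected planar CRS (meters).
    """


class NdviRangeError(ValidationError):
    """An NDVI value outside the physical range [-1, 1]."""


class DateFormatError(ValidationError):
    """An observation date that cannot be parsed as an ISO-8601 calendar date."""


class UnknownSensorError(ValidationError):
    """A sensor code outside {L5, L8}."""


class ReferentialError(ValidationError):
    """A foreign id (e.g. a classified garden_id) with no matching centroid."""


class ConfigurationError(ValueError):
    """An invalid configuration value or a precondition on the analysis universe
    (e.g. no village center present, empty reference table)."""


class ContractError(ValueError):
    """An internal call-contract violation (era/metric mismatch, duplicate era
    records for one garden)."""
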