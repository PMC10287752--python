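"""Exception hierarchy for editaudit."""


class EditAuditError(Exception):
    """Base class for all editaudit errors."""


class FormatError(EditAuditError):
    """A file does not conform to the expected format."""


class OrderingError(EditAuditError):
    """Records were required to be coordinate-sorted but are not."""


class CoordinateError(EditAuditError):
    """A genomic coordinate falls outside its contig."""


class ConsistencyError(EditAuditError):
    """A record contradicts the reference sequence or another record."""


class PlacementError(EditAuditError):
    """A requested placement (planted site, guide anchor) is invalid."""


class ConfigError(EditAuditError):
    """A configuration file or dictionary is missing or malformed."""


class ParameterError(EditAuditError):
    """An argument value is outside its admissible range."""
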