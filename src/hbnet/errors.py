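"""Exception hierarchy for the hbnet pipeline."""


class HbnetError(Exception):
    """Base class for all package errors."""


class FormatError(HbnetError):
    """Unknown or malformed file format."""


class DataError(HbnetError):
    """Payload violates an invariant (NaN/inf, truncation, shape)."""


class MetadataError(HbnetError):
    """Required metadata (sampling rate, signal kind) is missing."""


class ConsistencyError(HbnetError):
    """Cross-field inconsistency (e.g. membership names an undefined region)."""


class StabilityError(HbnetError):
    """A simulated VAR process is not covariance-stationary."""


class NumericalError(HbnetError):
    """A linear system is singular or an estimate is degenerate."""


class AlignmentError(HbnetError):
    """Two streams that must share a time base do not."""


class ProtocolError(HbnetError):
    """The evaluation protocol cannot be applied (e.g. too few samples per class)."""


class CapabilityError(HbnetError):
    """A feature kind was requested that the dataset cannot support."""


class ConfigError(HbnetError):
    """Configuration fails schema validation."""
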