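"""Exception types shared across the package."""


class AdherenceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AdherenceError):
    """A configuration value is invalid or inconsistent."""


class SchemaError(AdherenceError):
    """A play-log file does not match the documented CSV schema."""


class ValidationError(AdherenceError):
    """A data value violates a domain invariant (e.g. negative duration)."""


class ShortLogError(AdherenceError):
    """A participant log is too short for the requested train/test split."""

    def __init__(self, participant_id: str, n_days: int, required: int):
        self.participant_id = participant_id
        self.n_days = n_days
        self.required = required
        super().__init__(
            f"participant {participant_id!r} has {n_days} days of data; "
            f"{required} are required"
        )


class ShapeError(AdherenceError):
    """A network layer cannot be applied to its input shape."""


class ExtractorUnavailableError(AdherenceError):
    """The requested image feature extractor cannot be constructed."""
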