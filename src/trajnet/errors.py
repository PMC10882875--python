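"""Exception hierarchy shared across the package."""


class TrajnetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TrajnetError):
    """Input file does not match the documented column schema."""


class IntegrityError(TrajnetError):
    """Referential or uniqueness constraint violated."""


class CohortValidationError(TrajnetError):
    """One or more rows failed domain validation.

    Carries the full error report so callers can inspect every offending
    row rather than only the first.
    """

    def __init__(self, report: list[str]):
        self.report = list(report)
        super().__init__(
            f"{len(self.report)} validation error(s):\n" + "\n".join(self.report)
        )


class ConfigurationError(TrajnetError):
    """Invalid configuration value or combination."""


class EstimationError(TrajnetError):
    """A statistical estimate could not be computed."""


class UnidentifiableError(EstimationError):
    """Likelihood has no interior maximum (no discordant sets)."""
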