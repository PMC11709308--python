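"""Exception hierarchy for the fpscope pipeline.

Every stage raises a subclass of :class:`FpscopeError`, so callers (and the
CLI) can distinguish configuration problems from data problems with one
``except`` clause per family.
"""


class FpscopeError(Exception):
    """Base class for all fpscope errors."""


class ConfigError(FpscopeError):
    """Invalid configuration (taxonomy file, pipeline settings, simulation)."""


class TaxonomyConflictError(ConfigError):
    """The same fee code is claimed by two different services."""

    def __init__(self, code: str, service_a: str, service_b: str):
        self.code = code
        self.services = (service_a, service_b)
        super().__init__(
            f"fee code {code!r} is claimed by both {service_a!r} and {service_b!r}; "
            "sentinel codes must be unique to one service"
        )


class MalformedCodeError(FpscopeError):
    """A fee-code string is empty or unparseable."""


class SchemaError(FpscopeError):
    """An input file is missing required columns."""


class DuplicateRecordError(FpscopeError):
    """A physician id occurs more than once in a registry file."""


class ValidationError(FpscopeError):
    """A record or value violates a domain invariant."""


class UnknownRegionError(ValidationError):
    """A physician's health-region code is outside the configured universe."""


class ConsistencyError(FpscopeError):
    """Two pipeline artifacts that must describe the same cohort do not."""


class FixtureIntegrityError(FpscopeError):
    """The packaged reference summary fixture fails its checksum."""


class UndefinedPercentageError(FpscopeError):
    """Percentage requested with a zero denominator."""
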