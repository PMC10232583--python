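"""Exception hierarchy for schema, mapping and pipeline validation."""


class CsurvError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CsurvError):
    """A schema or mapping file violates its contract."""


class SchemaParseError(ValidationError):
    """The schema file could not be parsed."""


class EmptySchemaError(ValidationError):
    """The schema file defines no variables."""


class DuplicateVariableError(ValidationError):
    """Two schema rows share a variable id."""


class UnknownThemeError(ValidationError):
    """A variable references a theme number missing from the theme table."""


class UnknownStrategyError(ValidationError):
    """A strategy tag outside {SC, AT, S}."""


class CodebookError(ValidationError):
    """A codebook violates its invariants (duplicate codes, empty labels)."""


class MappingError(ValidationError):
    """Base for per-cohort mapping-file problems."""


class UnknownVariableError(MappingError):
    """A mapping rule targets a variable id absent from the schema."""


class DuplicateRuleError(MappingError):
    """More than one rule for the same (cohort, variable) pair."""


class CodebookViolationError(MappingError):
    """A recode table maps onto a code outside the target codebook."""


class StandardisationError(CsurvError):
    """Raised when z-standardisation or skewness is undefined for the input."""


class ConfigError(CsurvError):
    """Run configuration is inconsistent (e.g. rule kind vs. strategy)."""
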