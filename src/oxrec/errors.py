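"""Exception hierarchy shared across the package."""


class OxrecError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OxrecError):
    """A coefficient set, model spec, or cohort spec is invalid."""


class MissingDataError(OxrecError):
    """An operation received missing values it cannot handle itself."""


class SchemaError(OxrecError):
    """Tabular input does not match the expected column schema."""
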