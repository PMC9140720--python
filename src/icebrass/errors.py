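"""Exception hierarchy.

Errors are split by origin so callers (and the CLI exit-code mapping) can
distinguish bad configuration from bad data from broken reference assets.
"""


class IcebrassError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IcebrassError):
    """Invalid configuration value; message names the offending field."""


class SchemaError(IcebrassError):
    """Input table violates the expected column schema."""


class DataError(IcebrassError):
    """Input values are inconsistent (e.g. children dead exceeding parity)."""


class ReferenceDataError(IcebrassError):
    """Packaged reference data missing, corrupted, or failing its checksum."""
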