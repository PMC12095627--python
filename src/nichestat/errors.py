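"""Exception hierarchy shared across the package."""


class NichestatError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NichestatError, ValueError):
    """A file could not be parsed into the expected tabular/geometric schema."""


class ValidationError(NichestatError, ValueError):
    """Parsed data violates a schema invariant (duplicate ids, bad geometry...)."""


class ConfigurationError(NichestatError, ValueError):
    """A simulation or analysis configuration is infeasible or inconsistent."""
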