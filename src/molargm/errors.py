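"""Exception types shared across the package."""


class MolarGMError(Exception):
    """Base class for all package-specific errors."""


class TPSParseError(MolarGMError):
    """A TPS landmark file could not be parsed."""


class ValidationError(MolarGMError, ValueError):
    """Input data violate a dataset invariant."""


class DegenerateConfigurationError(MolarGMError, ValueError):
    """A landmark configuration is degenerate (e.g. all points coincide)."""


class EmptySelectionError(MolarGMError):
    """A filter removed every specimen."""
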