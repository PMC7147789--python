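"""Exception hierarchy for ncsim.

All errors raised by the package derive from :class:`NCSimError` so callers
can catch configuration and input problems with a single except clause.
"""


class NCSimError(Exception):
    """Base class for every error raised by ncsim."""


class ConfigurationError(NCSimError, ValueError):
    """A setting is missing, unknown, or inconsistent (e.g. unknown region,
    unset unit-conversion factor, unknown N2O accounting convention)."""


class InvalidQuantityError(NCSimError, ValueError):
    """A numeric input violates a precondition (non-finite, negative area,
    empty sample, cumulative < new, ...)."""


class BundleValidationError(NCSimError, ValueError):
    """A parameter bundle or scenario failed schema validation."""
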