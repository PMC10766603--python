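"""Exception hierarchy used across the package.

All trawlkit errors derive from :class:`TrawlkitError` so callers can catch
the package's failures with a single clause while letting programming errors
propagate.
"""


class TrawlkitError(Exception):
    """Base class for all trawlkit errors."""


class SchemaError(TrawlkitError):
    """A required column is missing or unresolvable in an input table."""


class IntegrityError(TrawlkitError):
    """Input data violates a structural invariant (duplicate haul ids with
    conflicting attributes, catches referencing unknown hauls, zero
    denominators that the quality filters should have removed, ...)."""


class DomainError(TrawlkitError, ValueError):
    """A numeric argument is outside its physical domain (non-positive
    distance, latitude beyond the poles, empty presence sequence, ...)."""


class FittingError(TrawlkitError):
    """The swept-area imputation model cannot be fitted (too few complete
    cases); callers should fall back to a fixed per-survey gear opening."""


class ConfigurationError(TrawlkitError):
    """A user-supplied configuration table is inconsistent (alias pointing
    outside the taxonomic backbone, invalid simulation settings, ...)."""
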