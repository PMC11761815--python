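"""Exception hierarchy.

Everything derives from :class:`MixtureMetaError` so callers can catch the
package's failures with one clause; the concrete classes map onto the
distinct failure modes of the formulas (gamma arguments must be positive,
pooled SD must exist, the k-1 divisor needs at least two studies, ...).
"""


class MixtureMetaError(Exception):
    """Base class for all mixturemeta errors."""


class InvalidDesignError(MixtureMetaError, ValueError):
    """Sample sizes violate the design constraints (e.g. n < 2)."""


class VarianceUndefinedError(MixtureMetaError, ValueError):
    """m <= 2: the variance formulas' gamma arguments are nonpositive."""


class MomentUndefinedError(MixtureMetaError, ValueError):
    """m <= r: the order-r moment does not exist."""


class DegenerateDataError(MixtureMetaError, ValueError):
    """Data admit no estimate (zero pooled SD, all variances nonpositive)."""


class InsufficientStudiesError(MixtureMetaError, ValueError):
    """Fewer studies than the estimator requires."""


class ConvergenceError(MixtureMetaError, RuntimeError):
    """Iterative estimation failed to converge."""


class SchemaError(MixtureMetaError, ValueError):
    """A study table does not match any recognized column schema."""
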