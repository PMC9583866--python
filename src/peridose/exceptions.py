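"""Exception hierarchy.

Everything raised by the package derives from :class:`PeridoseError`, so
callers (and the CLI) can catch one type.  The subclasses mirror the error
classes of the public operations: bad scalar parameters, queries outside the
model's validity region, malformed files, inconsistent grid/frame
configuration and infeasible calibration set-ups.
"""


class PeridoseError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PeridoseError, ValueError):
    """A scalar parameter violates its physical constraints (sign, range)."""


class OutOfValidityError(PeridoseError, ValueError):
    """A point query falls where the model is undefined (r below the guard)."""


class InvalidInputError(PeridoseError, ValueError):
    """An array/grid input violates a precondition (shape, positivity)."""


class ConfigurationError(PeridoseError, ValueError):
    """Grid geometry / frame / axis-map configuration is inconsistent."""


class FormatError(PeridoseError, ValueError):
    """A file does not follow its declared layout."""


class FitInfeasibleError(PeridoseError, ValueError):
    """Calibration cannot proceed (e.g. empty voxel mask)."""
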