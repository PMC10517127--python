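"""Typed exceptions used across the package.

All errors derive from :class:`PerivascError` so callers can catch the
package's failures with a single except clause.  Input problems (bad files,
bad geometry, bad parameters) derive from :class:`InputError`; the CLI maps
these to exit code 1 and everything else to exit code 2.
"""


class PerivascError(Exception):
    """Base class for all package errors."""


class InputError(PerivascError, ValueError):
    """User-supplied input is unusable (file, geometry, parameter)."""


class GeometryError(InputError):
    """Image geometry violates a precondition (e.g. odd side length)."""


class ParameterError(InputError):
    """A configuration parameter is out of its valid range."""


class EmptyMaskError(PerivascError):
    """An operation requiring a non-empty mask received an empty one.

    Raised instead of silently propagating NaN when no high-signal-strength
    area survives binarization and particle filtering.
    """


class DegenerateImageError(PerivascError):
    """Image content makes a metric undefined (e.g. zero overall mean)."""
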