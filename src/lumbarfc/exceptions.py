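"""Exception hierarchy.

All package errors derive from :class:`LumbarFCError` so callers can catch
validation problems (bad parameters, malformed inputs) separately from
study-level failures (e.g. every subject excluded by the motion screen).
"""


class LumbarFCError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(LumbarFCError, ValueError):
    """A numeric parameter is out of its valid range."""


class InputError(LumbarFCError, ValueError):
    """An input object violates a structural precondition."""


class DegenerateInputError(InputError):
    """Input is structurally valid but carries no usable signal
    (flat trace, zero variance, fewer than two cardiac peaks, ...)."""


class RangeError(LumbarFCError, ValueError):
    """A query point falls outside the supported interpolation window."""


class ConfigurationError(LumbarFCError, ValueError):
    """A pipeline configuration requests a component that was not provided."""


class InternalConsistencyError(LumbarFCError, RuntimeError):
    """An assembled object contradicts its own declared bookkeeping
    (e.g. design column count differs from the registry's expected count)."""


class LoadError(LumbarFCError, ValueError):
    """A file could not be loaded into a valid domain object.

    The message names the offending manifest field.
    """


class StudyError(LumbarFCError, RuntimeError):
    """A whole-cohort analysis cannot proceed (e.g. no subject survives
    the framewise-displacement exclusion rule)."""
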