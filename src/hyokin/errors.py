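"""Exception hierarchy shared across the package."""


class HyokinError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HyokinError):
    """An annotation file is malformed (message names the row/field)."""


class ValidationError(HyokinError):
    """A value violates a documented invariant (score range, scale, ...)."""


class MissingLandmarkError(HyokinError):
    """A landmark required to build the anatomical frame is absent."""


class DegenerateAxisError(HyokinError):
    """The vertebral landmarks do not define a usable coordinate axis."""


class NoMotionError(HyokinError):
    """No suprathreshold hyoid motion was detected in a trajectory."""


class DegenerateDataError(HyokinError):
    """A statistic is undefined for the given sample (n too small, constant)."""
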