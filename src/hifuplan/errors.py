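"""Exception hierarchy shared across the package.

``InputError`` covers malformed or missing user input (CLI exit code 1);
everything else raised by the library during computation maps to exit
code 2.
"""


class HifuPlanError(Exception):
    """Base class for all package errors."""


class InputError(HifuPlanError):
    """Missing or malformed input (files, masks, parameter values)."""


class ValidationError(InputError):
    """An anatomy/label-map invariant does not hold."""


class GeometryError(InputError):
    """Volumes disagree on shape/spacing/origin, or a non-axis-aligned grid."""


class ConfigError(InputError):
    """Non-physical or inconsistent device/phantom configuration."""


class PoseError(HifuPlanError):
    """A transducer pose lies outside the device motion limits."""


class FitError(HifuPlanError):
    """A transform fit is underdetermined or degenerate."""


class SegmentationError(HifuPlanError):
    """Automatic segmentation could not produce a usable mask."""


class PositioningError(HifuPlanError):
    """Home-position estimation failed (e.g. the isocentre column misses the body)."""
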