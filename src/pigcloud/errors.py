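"""Exception hierarchy for pipeline failures.

All data-level failures derive from :class:`PigcloudError` so the CLI can
map them to exit code 1 while genuine usage errors stay at exit code 2.
"""


class PigcloudError(Exception):
    """Base class for data and configuration errors raised by pigcloud."""


class InvalidDepthError(PigcloudError):
    """A depth value of 0 (no sensor return) was used where a valid depth is required."""


class RegistrationMismatchError(PigcloudError):
    """RGB, depth and mask rasters that must share a pixel grid do not."""


class AnnotationError(PigcloudError):
    """Inconsistent instance annotations (e.g. mask colour missing from the colour list)."""


class DegenerateGeometryError(PigcloudError):
    """Too few or collinear correspondences for a rigid fit."""


class EmptyCloudError(PigcloudError):
    """An operation that needs points received an empty cloud."""


class FormatError(PigcloudError):
    """An on-disk file does not match the expected format."""


class UndefinedMetricError(PigcloudError):
    """A metric is undefined for the given counts (e.g. precision with TP+FP=0)."""


class PlacementError(PigcloudError):
    """Synthetic scene generation could not place all animals within retry budget."""
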