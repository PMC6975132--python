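"""Exception hierarchy for the FMVM toolkit.

Every error raised by the package derives from :class:`FmvmError` so that the
full-field pipeline can record per-capillary failures without swallowing
unrelated bugs.
"""


class FmvmError(Exception):
    """Base class for all FMVM errors."""


class ConfigError(FmvmError, ValueError):
    """Invalid configuration (non-positive fps, too few frames, ...)."""


class InputError(FmvmError, ValueError):
    """Invalid runtime input (empty list, length mismatch, ...)."""


class ParseError(FmvmError, ValueError):
    """A box file or report file failed to parse; names the offending record."""


class NoVesselError(FmvmError):
    """Vessel segmentation found no component of sufficient area."""


class ClosedLoopSkeletonError(FmvmError):
    """Skeleton has no endpoints (reduces to a cycle)."""


class BranchingSkeletonError(FmvmError):
    """Skeleton keeps more than two endpoints after spur pruning."""


class DegenerateSkeletonError(FmvmError):
    """Spur pruning eliminated the whole skeleton."""


class NoStreaksError(FmvmError):
    """No streak in the kymograph satisfies the length/darkness criteria."""


class OutOfBoundsError(FmvmError):
    """A skeleton point lies outside the video frame."""
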