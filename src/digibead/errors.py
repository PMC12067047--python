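"""Exception hierarchy for the digital bead-assay pipeline."""


class DigibeadError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DigibeadError, ValueError):
    """A parameter violates its documented domain."""


class PlacementError(DigibeadError):
    """Bead placement failed: requested density exceeds packing feasibility."""


class InsufficientBlankError(DigibeadError):
    """Fewer blank beads than the configured floor for a Gaussian fit."""


class DegenerateBlankError(DigibeadError):
    """Blank intensities have zero variance; no threshold can be defined."""


class NoBeadsError(DigibeadError):
    """An operation requiring at least one bead received none."""


class NoFramesError(DigibeadError):
    """An operation requiring at least one frame received none."""


class FitFailureError(DigibeadError):
    """Dose-response fit did not converge from any start, or is degenerate."""


class LODUndefinedError(DigibeadError):
    """The LOD response level lies outside the fitted asymptote interval."""


class StructuralError(DigibeadError):
    """Inconsistent container structure (e.g. channel count mismatch)."""
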