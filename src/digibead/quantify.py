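"""Digital and analog readouts from per-bead intensities.

Digital analysis follows the Poisson single-molecule counting convention:
the blank (zero-analyte) condition's per-bead maximum intensities are fitted
to a Gaussian; beads in analyte conditions whose maximum intensity exceeds
the blank mean + 2 SD are "on"; the on-fraction ``f_on`` is inverted through
Poisson statistics to the average number of molecules per bead,
``AMB = -ln(1 - f_on)``. Analog analysis is the grand mean pixel intensity
over all fluorescence frames, beads and background alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateBlankError,
    InsufficientBlankError,
    InvalidParameterError,
    NoBeadsError,
    NoFramesError,
)

__all__ = [
    "BlankModel",
    "DigitalResult",
    "AnalogResult",
    "fit_blank",
    "classify_beads",
    "amb_from_f_on",
    "compute_amb",
    "analog_readout",
]


def amb_from_f_on(f_on: float) -> float:
    """Poisson inversion of an on-fraction: -ln(1 - f_on).

    The continuous identity behind :func:`compute_amb`; for f_on = 1 - e^-lam
    it returns lam exactly (up to floating point).
    """
    if not 0.0 <= f_on < 1.0:
        raise InvalidParameterError(f"f_on must lie in [0, 1), got {f_on!r}")
    return -math.log1p(-f_on)


@dataclass(frozen=True)
class BlankModel:
    """Gaussian model of blank-bead maximum intensities and the on/off threshold."""

    mu_blank: float
    sigma_blank: float
    threshold: float
    n_blank_beads: int


@dataclass(frozen=True)
class DigitalResult:
    """Digital readout: on/off counts, on-fraction, and the Poisson-inverted AMB."""

    n_on: int
    n_total: int
    f_on: float
    amb: float
    saturated: bool


@dataclass(frozen=True)
class AnalogResult:
    """Analog readout: mean pixel intensity over all fluorescence frames."""

    mean_intensity: float
    n_frames: int


def fit_blank(blank_intensities: Sequence[float], min_beads: int = 30) -> BlankModel:
    """Fit a Gaussian to blank-bead maximum intensities.

    Maximum-likelihood moment estimators are used (sample mean; SD with the
    n-1 denominator); the on/off threshold is mu + 2*sigma.
    """
    x = np.asarray(blank_intensities, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < min_beads:
        raise InsufficientBlankError(
            f"need at least {min_beads} blank beads for a Gaussian fit, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("blank intensities contain non-finite values")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    if sigma <= 0:
        raise DegenerateBlankError("blank intensities have zero variance")
    return BlankModel(
        mu_blank=mu, sigma_blank=sigma, threshold=mu + 2.0 * sigma, n_blank_beads=int(x.size)
    )


def classify_beads(intensities: Sequence[float], blank: BlankModel) -> tuple[int, int]:
    """Count "on" beads: maximum intensity strictly above the blank threshold."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise NoBeadsError("no bead intensities to classify")
    if not math.isfinite(blank.threshold):
        raise InvalidParameterError("blank threshold is not finite")
    n_on = int(np.count_nonzero(x > blank.threshold))
    return n_on, int(x.size)


def compute_amb(n_on: int, n_total: int) -> DigitalResult:
    """Poisson inversion of the on-fraction: AMB = -ln(1 - f_on).

    When ``f_on`` reaches within one bead of saturation (all beads on, or
    all but one), the estimate is capped at the value for ``n_total - 0.5``
    on beads and flagged ``saturated`` so downstream calibration never sees
    an infinite AMB.
    """
    if n_on < 0 or n_total <= 0 or n_on > n_total:
        raise InvalidParameterError(f"invalid counts n_on={n_on!r}, n_total={n_total!r}")
    f_on = n_on / n_total
    saturated = f_on >= 1.0 - 1.0 / n_total
    if saturated:
        amb = -math.log(1.0 - (n_total - 0.5) / n_total)
    else:
        amb = amb_from_f_on(f_on)
    return DigitalResult(n_on=int(n_on), n_total=int(n_total), f_on=f_on, amb=amb, saturated=saturated)


def analog_readout(fluorescence_frames: Sequence[np.ndarray]) -> AnalogResult:
    """Grand mean pixel intensity over all fluorescence frames.

    Includes beads and background alike; frames share one shape, so the
    unweighted grand mean equals the mean of per-frame means and is
    invariant to frame order.
    """
    if len(fluorescence_frames) == 0:
        raise NoFramesError("no fluorescence frames")
    shape = np.asarray(fluorescence_frames[0]).shape
    total = 0.0
    n_px = 0
    for f in fluorescence_frames:
        a = np.asarray(f, dtype=float)
        if a.shape != shape:
            raise InvalidParameterError("all fluorescence frames must share one shape")
        total += float(a.sum())
        n_px += a.size
    return AnalogResult(mean_intensity=total / n_px, n_frames=len(fluorescence_frames))
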