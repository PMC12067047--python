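"""Circular bead detection and per-bead fluorescence extraction.

Beads are located in the localization channel (brightfield: dark disks on a
bright background; darkfield: bright disks on dark) with a gradient-based
circular Hough accumulator (canny edges + ``skimage.transform.hough_circle``),
then each detected circle is overlaid on the co-registered fluorescence
frame and the maximum pixel intensity inside the circle is read out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import InvalidParameterError, StructuralError
from .synthetic import FrameSet, OpticsParams

__all__ = [
    "DetectionParams",
    "BeadDetection",
    "detect_beads",
    "extract_bead_intensity",
    "detect_frameset",
    "detections_to_dataframe",
]


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the circular-object detector.

    ``sensitivity`` is the normalized Hough-accumulator threshold in (0, 1]:
    a complete, well-contrasted circle scores close to 1, so lower values
    admit weaker (partial / noisy) circles. ``polarity`` selects dark disks
    (brightfield) or bright disks (darkfield). Detections closer than
    ``min_separation`` pixels are merged keeping the stronger peak.
    """

    radius_min: float
    radius_max: float
    sensitivity: float = 0.45
    polarity: str = "dark"
    min_separation: float = 6.0
    refine_centers: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.radius_min <= self.radius_max:
            raise InvalidParameterError(
                f"need 1 <= radius_min <= radius_max, got "
                f"({self.radius_min!r}, {self.radius_max!r})"
            )
        if not 0.0 < self.sensitivity <= 1.0:
            raise InvalidParameterError(f"sensitivity must lie in (0, 1], got {self.sensitivity!r}")
        if self.polarity not in ("dark", "bright"):
            raise InvalidParameterError(f"polarity must be 'dark' or 'bright', got {self.polarity!r}")
        if self.min_separation <= 0:
            raise InvalidParameterError(f"min_separation must be > 0, got {self.min_separation!r}")

    @classmethod
    def from_optics(cls, optics: OpticsParams, **overrides) -> "DetectionParams":
        """Defaults matched to a simulator configuration: radius +/- 40%,
        separation 1.5x the nominal radius, polarity from the modality."""
        r = optics.bead_radius_px
        kw = dict(
            radius_min=max(1.0, 0.6 * r),
            radius_max=1.4 * r,
            polarity="dark" if optics.modality == "brightfield" else "bright",
            min_separation=1.5 * r,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class BeadDetection:
    """One detected bead: sub-pixel center, radius, and its fluorescence max."""

    center: tuple[float, float]
    radius: float
    max_intensity: float
    frame_index: int = 0


def _refine_center(
    img: np.ndarray, row: float, col: float, radius: float, radius_max: float
) -> tuple[float, float, float]:
    """Refine a candidate circle to the centroid of its thresholded disk.

    Takes the connected component of above-half-contrast pixels nearest the
    Hough peak inside a window sized for the largest admissible bead; on a
    filled disk the component is the disk itself, so its centroid recovers
    the center to well under a pixel and its area yields a radius estimate
    (sqrt(area/pi)). Falls back to the raw peak when the window is flat.
    """
    h, w = img.shape
    pad = int(math.ceil(radius_max)) + 3
    r0, r1 = max(0, int(round(row)) - pad), min(h, int(round(row)) + pad + 1)
    c0, c1 = max(0, int(round(col)) - pad), min(w, int(round(col)) + pad + 1)
    win = img[r0:r1, c0:c1]
    lo, hi = float(win.min()), float(win.max())
    if hi - lo <= 0:
        return row, col, radius
    labels, n_comp = ndimage.label(win >= lo + 0.5 * (hi - lo))
    if n_comp == 0:
        return row, col, radius
    ir = min(max(int(round(row)) - r0, 0), win.shape[0] - 1)
    ic = min(max(int(round(col)) - c0, 0), win.shape[1] - 1)
    comp = labels[ir, ic]
    if comp == 0:
        rr, cc = np.nonzero(labels)
        k = int(np.argmin((rr - (row - r0)) ** 2 + (cc - (col - c0)) ** 2))
        comp = labels[rr[k], cc[k]]
    rr, cc = np.nonzero(labels == comp)
    r_est = math.sqrt(rr.size / math.pi)
    return float(np.mean(rr) + r0), float(np.mean(cc) + c0), r_est


def detect_beads(
    localization_frame: np.ndarray, params: DetectionParams
) -> list[tuple[tuple[float, float], float]]:
    """Detect circular beads in one localization frame.

    Returns a list of ``((row, col), radius)`` pairs. Circles whose disk
    extends past the frame border are discarded; peaks closer than
    ``min_separation`` are merged greedily, keeping the stronger
    accumulator vote. An empty or constant frame yields an empty list.
    """
    img = np.asarray(localization_frame, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError(f"frame must be 2-D, got ndim={img.ndim}")
    if not np.all(np.isfinite(img)):
        raise InvalidParameterError("frame contains non-finite values")
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return []
    # a frame whose full range is explained by pixel noise carries no objects;
    # without this guard, normalization would stretch noise to full contrast
    mad = float(np.median(np.abs(img - np.median(img))))
    if hi - lo <= 10.0 * 1.4826 * mad:
        return []

    norm = (img - lo) / (hi - lo)
    if params.polarity == "dark":
        norm = 1.0 - norm

    edges = canny(norm, sigma=1.2)
    if not edges.any():
        return []
    r_lo = max(1, int(math.ceil(params.radius_min)))
    r_hi = max(r_lo, int(math.floor(params.radius_max)))
    radii = np.arange(r_lo, r_hi + 1)
    accum = hough_circle(edges, radii)
    # generous peak budget; the sensitivity threshold and the merge prune it
    max_peaks = max(64, int(edges.sum() / (2 * math.pi * radii.min())) + 16)
    accums, cx, cy, rad = hough_circle_peaks(
        accum,
        radii,
        threshold=params.sensitivity,
        num_peaks=max_peaks,
        total_num_peaks=max_peaks,
        normalize=True,
    )
    if len(accums) == 0:
        return []

    # Refine every candidate before merging: duplicate votes for one bead
    # (neighboring radii / off-center small circles) collapse onto the same
    # centroid and are then merged by min_separation, strongest peak first.
    # Candidates whose refined disk is far smaller than the admissible range
    # are noise specks, not beads, and are dropped.
    cand = []
    for i in range(len(accums)):
        row, col, r = float(cy[i]), float(cx[i]), float(rad[i])
        if params.refine_centers:
            row, col, r_est = _refine_center(norm, row, col, r, params.radius_max)
            if r_est < params.radius_min - 1.0:
                continue
            r = min(max(r_est, params.radius_min), params.radius_max)
        cand.append((float(accums[i]), row, col, r))
    cand.sort(key=lambda t: t[0], reverse=True)

    kept: list[tuple[float, float, float]] = []
    for _, row, col, r in cand:
        if any(math.hypot(row - kr, col - kc) < params.min_separation for kr, kc, _ in kept):
            continue
        kept.append((row, col, r))

    h, w = img.shape
    out: list[tuple[tuple[float, float], float]] = []
    for row, col, r in kept:
        if row - r < 0 or col - r < 0 or row + r > h - 1 or col + r > w - 1:
            continue  # disk extends past the border
        out.append(((row, col), r))
    return out


def extract_bead_intensity(
    detections: list[tuple[tuple[float, float], float]],
    fluorescence_frame: np.ndarray,
    frame_index: int = 0,
) -> list[BeadDetection]:
    """Read each bead's maximum fluorescence pixel inside its circle.

    A pixel belongs to the circle when its center lies within the radius
    (boundary inclusive). Detection order is preserved.
    """
    flu = np.asarray(fluorescence_frame, dtype=float)
    if flu.ndim != 2:
        raise InvalidParameterError(f"fluorescence frame must be 2-D, got ndim={flu.ndim}")
    h, w = flu.shape
    out = []
    for (row, col), radius in detections:
        r0 = max(0, int(math.floor(row - radius)))
        r1 = min(h, int(math.ceil(row + radius)) + 1)
        c0 = max(0, int(math.floor(col - radius)))
        c1 = min(w, int(math.ceil(col + radius)) + 1)
        if r0 >= r1 or c0 >= c1:
            raise InvalidParameterError(
                f"circle at ({row:.1f}, {col:.1f}) r={radius:.1f} lies outside the frame"
            )
        rr, cc = np.mgrid[r0:r1, c0:c1]
        mask = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
        if not mask.any():
            raise InvalidParameterError(
                f"circle at ({row:.1f}, {col:.1f}) r={radius:.1f} covers no pixel centers"
            )
        out.append(
            BeadDetection(
                center=(row, col),
                radius=radius,
                max_intensity=float(flu[r0:r1, c0:c1][mask].max()),
                frame_index=frame_index,
            )
        )
    return out


def detect_frameset(frames: FrameSet, params: DetectionParams) -> list[BeadDetection]:
    """Run detection + intensity extraction over every frame pair."""
    if len(frames.localization_frames) != len(frames.fluorescence_frames):
        raise StructuralError("localization/fluorescence channel count mismatch")
    out: list[BeadDetection] = []
    for f, (loc, flu) in enumerate(zip(frames.localization_frames, frames.fluorescence_frames)):
        circles = detect_beads(loc, params)
        out.extend(extract_bead_intensity(circles, flu, frame_index=f))
    return out


def detections_to_dataframe(detections: list[BeadDetection]) -> pd.DataFrame:
    """Tabulate detections as (frame_index, row, col, radius, max_intensity)."""
    return pd.DataFrame(
        [
            {
                "frame_index": d.frame_index,
                "row": d.center[0],
                "col": d.center[1],
                "radius": d.radius,
                "max_intensity": d.max_intensity,
            }
            for d in detections
        ],
        columns=["frame_index", "row", "col", "radius", "max_intensity"],
    )
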