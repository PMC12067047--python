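"""Synthetic digital bead-assay generator.

Simulates the statistical structure a compartmentalization-free digital
bead assay produces: analyte molecules load onto magnetic beads following
Poisson statistics with mean ``lambda = capture_coeff * concentration *
labeling_efficiency``; amplified reporters make any bead carrying at least
one labeled molecule brightly "on" in fluorescence, while unloaded beads sit
at the blank background level. A random subset of the bead population
(typically ~21%, spread over ~100-150 fields of view) is rendered into
paired localization (brightfield or darkfield) and fluorescence rasters,
with per-bead ground truth retained so every downstream stage of the
pipeline can be scored against a known answer.

All randomness is owned by explicit integer seeds; identical inputs and
seeds reproduce identical outputs bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, PlacementError

__all__ = [
    "AssayParams",
    "BeadPopulation",
    "OpticsParams",
    "FrameSet",
    "simulate_bead_loading",
    "render_frames",
    "simulate_dilution_series",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = ["frame_index", "row", "col", "radius", "on", "peak_intensity", "count"]


@dataclass(frozen=True)
class AssayParams:
    """Assay-level parameters governing molecule loading onto beads.

    Parameters
    ----------
    concentration
        Analyte concentration in ng/mL (>= 0).
    capture_coeff
        Molecules captured per bead per (ng/mL) of analyte (kappa, > 0).
    n_beads
        Total number of beads in the assay (> 0).
    labeling_efficiency
        Probability that a captured molecule yields an amplified,
        fluorescently labeled product (0-1).
    seed
        RNG seed; identical seeds reproduce identical populations.
    """

    concentration: float
    capture_coeff: float
    n_beads: int
    labeling_efficiency: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise InvalidParameterError(
                f"concentration must be finite and >= 0, got {self.concentration!r}"
            )
        if not math.isfinite(self.capture_coeff) or self.capture_coeff <= 0:
            raise InvalidParameterError(
                f"capture_coeff must be finite and > 0, got {self.capture_coeff!r}"
            )
        if int(self.n_beads) != self.n_beads or self.n_beads <= 0:
            raise InvalidParameterError(f"n_beads must be a positive integer, got {self.n_beads!r}")
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise InvalidParameterError(
                f"labeling_efficiency must lie in [0, 1], got {self.labeling_efficiency!r}"
            )

    @property
    def lam(self) -> float:
        """Poisson mean of labeled molecules per bead."""
        return self.concentration * self.capture_coeff * self.labeling_efficiency


@dataclass(frozen=True)
class BeadPopulation:
    """Ground-truth bead population: per-bead labeled-molecule counts."""

    counts: np.ndarray
    on_truth: np.ndarray
    lambda_true: float

    @property
    def n_beads(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class OpticsParams:
    """Rendering parameters for paired localization/fluorescence rasters.

    Intensities are in camera arbitrary units on a ``bit_depth``-bit scale.
    ``blank_mean``/``blank_sd`` parameterize the Gaussian peak intensity of
    "off" beads; "on" beads draw their peak from
    LogNormal(on_intensity_mu, on_intensity_sigma). ``background_drift_sd``
    is the SD of a per-frame background offset emulating field-to-field
    illumination and autofluorescence variation across a scanned slide.
    """

    image_shape: tuple[int, int] = (256, 256)
    bead_radius_px: float = 4.0
    radius_jitter: float = 0.05
    blank_mean: float = 8000.0
    blank_sd: float = 600.0
    on_intensity_mu: float = math.log(30000.0)
    on_intensity_sigma: float = 0.35
    background_level: float = 3000.0
    read_noise_sd: float = 50.0
    background_drift_sd: float = 150.0
    bit_depth: int = 16
    modality: str = "brightfield"
    check_separable: bool = True

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise InvalidParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth!r}")
        if self.bead_radius_px < 2:
            raise InvalidParameterError(
                f"bead_radius_px must be >= 2, got {self.bead_radius_px!r}"
            )
        if self.modality not in ("brightfield", "darkfield"):
            raise InvalidParameterError(
                f"modality must be 'brightfield' or 'darkfield', got {self.modality!r}"
            )
        if self.check_separable:
            on_median = math.exp(self.on_intensity_mu)
            if on_median <= self.blank_mean + 2.0 * self.blank_sd:
                raise InvalidParameterError(
                    "on-bead median intensity must exceed blank_mean + 2*blank_sd "
                    "(set check_separable=False to deliberately test overlap)"
                )

    @property
    def full_scale(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass
class FrameSet:
    """Co-registered localization/fluorescence frame pairs with ground truth.

    Coordinates are 0-based (row, col), center-of-pixel convention. The
    truth table has one row per rendered bead with columns
    ``frame_index, row, col, radius, on, peak_intensity, count``; every
    truth center lies at least its radius inside the frame bounds.
    """

    localization_frames: list[np.ndarray]
    fluorescence_frames: list[np.ndarray]
    truth_table: pd.DataFrame
    optics: OpticsParams

    def __post_init__(self) -> None:
        if len(self.localization_frames) != len(self.fluorescence_frames):
            raise InvalidParameterError(
                "localization and fluorescence channels must have the same frame count"
            )

    @property
    def n_frames(self) -> int:
        return len(self.localization_frames)


def simulate_bead_loading(params: AssayParams) -> BeadPopulation:
    """Draw per-bead labeled-molecule counts from the Poisson loading model.

    Each bead independently carries Poisson(lambda) labeled molecules with
    lambda = capture_coeff * concentration * labeling_efficiency; a bead is
    "on" iff it carries at least one.
    """
    rng = np.random.default_rng(params.seed)
    counts = rng.poisson(params.lam, size=params.n_beads).astype(np.int64)
    return BeadPopulation(counts=counts, on_truth=counts >= 1, lambda_true=params.lam)


def _place_beads_in_frame(
    k: int,
    optics: OpticsParams,
    rng: np.random.Generator,
    frame_index: int,
    allow_overlap: bool,
    max_attempts_per_bead: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample k non-overlapping bead centers; returns (centers, radii)."""
    h, w = optics.image_shape
    centers = np.empty((k, 2), dtype=float)
    radii = np.empty(k, dtype=float)
    for i in range(k):
        r = max(2.0, optics.bead_radius_px * (1.0 + optics.radius_jitter * rng.standard_normal()))
        margin = r + 1.0
        if 2 * margin >= h or 2 * margin >= w:
            raise PlacementError(f"frame {frame_index}: bead radius {r:.1f} px exceeds frame size")
        placed = False
        for _ in range(max_attempts_per_bead):
            row = rng.uniform(margin, h - 1 - margin)
            col = rng.uniform(margin, w - 1 - margin)
            if not allow_overlap and i > 0:
                d = np.hypot(centers[:i, 0] - row, centers[:i, 1] - col)
                min_d = 2.2 * np.maximum(radii[:i], r)
                if np.any(d < min_d):
                    continue
            centers[i] = (row, col)
            radii[i] = r
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"frame {frame_index}: could not place bead {i + 1}/{k} after "
                f"{max_attempts_per_bead} attempts; bead density exceeds packing feasibility"
            )
    return centers, radii


def _disk_mask(shape: tuple[int, int], row: float, col: float, radius: float):
    """Bounding-box slice and boolean mask of pixel centers within the disk."""
    r0 = max(0, int(math.floor(row - radius)))
    r1 = min(shape[0], int(math.ceil(row + radius)) + 1)
    c0 = max(0, int(math.floor(col - radius)))
    c1 = min(shape[1], int(math.ceil(col + radius)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    mask = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    return (slice(r0, r1), slice(c0, c1)), mask


def render_frames(
    population: BeadPopulation,
    optics: OpticsParams,
    n_frames: int,
    imaged_fraction: float = 0.21,
    seed: int = 0,
    allow_overlap: bool = False,
) -> FrameSet:
    """Render a random subset of the bead population into frame pairs.

    A Binomial(n_beads, imaged_fraction) subset of beads is distributed
    uniformly at random across ``n_frames`` fields of view. Centers are
    rejection-sampled so that no two beads in a frame are closer than 2.2x
    their radius and no disk clips the frame border (``allow_overlap=True``
    disables the spacing rule for stress tests). The localization channel
    renders filled disks contrasted against the background (dark-on-bright
    for brightfield, bright-on-dark for darkfield); the fluorescence channel
    renders each bead as a uniform disk at its drawn peak intensity over the
    (per-frame drifted) background, plus per-pixel Gaussian read noise,
    clipped to the bit range.
    """
    if n_frames < 1:
        raise InvalidParameterError(f"n_frames must be >= 1, got {n_frames!r}")
    if not 0.0 < imaged_fraction <= 1.0:
        raise InvalidParameterError(
            f"imaged_fraction must lie in (0, 1], got {imaged_fraction!r}"
        )

    rng = np.random.default_rng(seed)
    n = population.n_beads
    h, w = optics.image_shape
    fs = optics.full_scale

    if optics.modality == "brightfield":
        loc_bg, loc_disk = 0.72 * fs, 0.28 * fs
    else:
        loc_bg, loc_disk = 0.08 * fs, 0.65 * fs

    n_imaged = int(rng.binomial(n, imaged_fraction)) if n > 0 else 0
    imaged_idx = rng.choice(n, size=n_imaged, replace=False) if n_imaged > 0 else np.empty(0, int)
    frame_of = rng.integers(0, n_frames, size=n_imaged)

    loc_frames: list[np.ndarray] = []
    flu_frames: list[np.ndarray] = []
    rows: list[dict] = []
    for f in range(n_frames):
        bead_ids = imaged_idx[frame_of == f]
        k = bead_ids.size
        centers, radii = _place_beads_in_frame(k, optics, rng, f, allow_overlap)

        loc = np.full((h, w), loc_bg, dtype=float)
        drift = rng.normal(0.0, optics.background_drift_sd) if optics.background_drift_sd > 0 else 0.0
        flu = np.full((h, w), optics.background_level + drift, dtype=float)

        for i, bead in enumerate(bead_ids):
            on = bool(population.on_truth[bead])
            if on:
                peak = float(rng.lognormal(optics.on_intensity_mu, optics.on_intensity_sigma))
            else:
                peak = float(rng.normal(optics.blank_mean, optics.blank_sd))
            box, mask = _disk_mask((h, w), centers[i, 0], centers[i, 1], radii[i])
            loc[box][mask] = loc_disk
            flu[box][mask] = peak
            rows.append(
                {
                    "frame_index": f,
                    "row": centers[i, 0],
                    "col": centers[i, 1],
                    "radius": radii[i],
                    "on": on,
                    "peak_intensity": min(max(peak, 0.0), fs),
                    "count": int(population.counts[bead]),
                }
            )

        if optics.read_noise_sd > 0:
            loc += rng.normal(0.0, optics.read_noise_sd, size=(h, w))
            flu += rng.normal(0.0, optics.read_noise_sd, size=(h, w))
        loc_frames.append(np.clip(loc, 0.0, fs))
        flu_frames.append(np.clip(flu, 0.0, fs))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth["on"] = truth["on"].astype(bool)
    return FrameSet(
        localization_frames=loc_frames,
        fluorescence_frames=flu_frames,
        truth_table=truth,
        optics=optics,
    )


@dataclass
class DilutionCondition:
    """One (concentration, replicate) cell of a simulated dilution series."""

    concentration: float
    replicate: int
    lambda_true: float
    frameset: FrameSet


def simulate_dilution_series(
    concentrations: list[float],
    params_base: AssayParams,
    optics: OpticsParams,
    replicates: int = 3,
    seed: int = 0,
    n_frames: int = 120,
    imaged_fraction: float = 0.21,
) -> tuple[list[DilutionCondition], pd.DataFrame]:
    """Simulate a calibration dilution series with replicates.

    One FrameSet is generated per (concentration, replicate) pair, with
    loading and rendering seeds derived reproducibly from the master seed.
    Returns the conditions and a manifest DataFrame mapping each cell to its
    concentration, replicate, true lambda, seeds, and rendered bead count.
    """
    if len(concentrations) == 0:
        raise InvalidParameterError("concentration list must not be empty")
    conc = [float(c) for c in concentrations]
    if any(c < 0 or not math.isfinite(c) for c in conc):
        raise InvalidParameterError("concentrations must be finite and non-negative")
    if sorted(conc) != conc:
        raise InvalidParameterError("concentrations must be sorted ascending")
    if replicates < 1:
        raise InvalidParameterError(f"replicates must be >= 1, got {replicates!r}")

    n_cells = len(conc) * replicates
    child = np.random.SeedSequence(seed).generate_state(2 * n_cells, dtype=np.uint32)
    child = (child & 0x7FFFFFFF).astype(np.int64)

    conditions: list[DilutionCondition] = []
    manifest_rows = []
    i = 0
    for c in conc:
        for rep in range(1, replicates + 1):
            load_seed, render_seed = int(child[2 * i]), int(child[2 * i + 1])
            i += 1
            p = replace(params_base, concentration=c, seed=load_seed)
            pop = simulate_bead_loading(p)
            fset = render_frames(
                pop, optics, n_frames=n_frames, imaged_fraction=imaged_fraction, seed=render_seed
            )
            conditions.append(
                DilutionCondition(
                    concentration=c, replicate=rep, lambda_true=p.lam, frameset=fset
                )
            )
            manifest_rows.append(
                {
                    "concentration": c,
                    "replicate": rep,
                    "lambda_true": p.lam,
                    "load_seed": load_seed,
                    "render_seed": render_seed,
                    "n_frames": n_frames,
                    "n_rendered_beads": len(fset.truth_table),
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    return conditions, manifest
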