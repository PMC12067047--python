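import dataclasses

import numpy as np
import pytest

from digibead import AssayParams, DetectionParams, OpticsParams, render_frames, simulate_bead_loading


@pytest.fixture(scope="session")
def default_optics() -> OpticsParams:
    return OpticsParams()


@pytest.fixture(scope="session")
def quiet_optics(default_optics) -> OpticsParams:
    """Noise-free rendering: no read noise, no frame-to-frame background drift."""
    return dataclasses.replace(default_optics, read_noise_sd=0.0, background_drift_sd=0.0)


@pytest.fixture(scope="session")
def default_detection(default_optics) -> DetectionParams:
    return DetectionParams.from_optics(default_optics)


def make_frameset(optics, n_beads, n_frames, seed, lam=1.0, imaged_fraction=1.0):
    """Small ground-truthed FrameSet for detection tests."""
    params = AssayParams(
        concentration=lam, capture_coeff=1.0, n_beads=n_beads, seed=seed
    )
    pop = simulate_bead_loading(params)
    return render_frames(
        pop, optics, n_frames=n_frames, imaged_fraction=imaged_fraction, seed=seed + 1
    )


def score_detections(frameset, detections, tol=2.0):
    """Greedy one-to-one matching of detections to ground truth within tol px.

    Returns (recall, precision, matched center errors).
    """
    truth = frameset.truth_table
    matched = set()
    errors = []
    for det in detections:
        sub = truth[truth.frame_index == det.frame_index]
        if sub.empty:
            continue
        dist = np.hypot(sub.row - det.center[0], sub.col - det.center[1])
        j = dist.idxmin()
        if dist[j] <= tol and (det.frame_index, j) not in matched:
            matched.add((det.frame_index, j))
            errors.append(float(dist[j]))
    n_truth, n_det = len(truth), len(detections)
    recall = len(matched) / n_truth if n_truth else 1.0
    precision = len(matched) / n_det if n_det else 1.0
    return recall, precision, np.asarray(errors)
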