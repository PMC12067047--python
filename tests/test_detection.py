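import dataclasses

import numpy as np
import pytest

from digibead import (
    DetectionParams,
    detect_beads,
    detect_frameset,
    extract_bead_intensity,
)
from digibead.errors import InvalidParameterError, StructuralError

from conftest import make_frameset, score_detections


def draw_disks(shape, circles, bg=200.0, disk=60.0):
    """Explicit dark-disk raster: circles = [(row, col, radius), ...]."""
    img = np.full(shape, bg)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for row, col, rad in circles:
        img[(rr - row) ** 2 + (cc - col) ** 2 <= rad**2] = disk
    return img


class TestDetectBeads:
    def test_blank_and_constant_frames_yield_empty(self):
        params = DetectionParams(radius_min=3, radius_max=8)
        assert detect_beads(np.full((64, 64), 100.0), params) == []
        rng = np.random.default_rng(0)
        noise_only = 100.0 + rng.normal(0, 2, size=(64, 64))
        assert detect_beads(noise_only, params) == []

    def test_three_known_disks_recovered_within_a_pixel(self):
        truth = [(20.0, 20.0, 6.0), (50.0, 70.0, 6.0), (80.0, 30.0, 6.0)]
        img = draw_disks((100, 100), truth)
        found = detect_beads(img, DetectionParams(radius_min=4, radius_max=9))
        assert len(found) == 3
        for row, col, rad in truth:
            dists = [np.hypot(r - row, c - col) for (r, c), _ in found]
            k = int(np.argmin(dists))
            assert dists[k] <= 1.0
            assert abs(found[k][1] - rad) <= 1.0

    def test_dense_noisy_regime_recall(self, default_optics, default_detection):
        fs = make_frameset(default_optics, n_beads=200, n_frames=5, seed=21)
        dets = detect_frameset(fs, default_detection)
        recall, precision, _ = score_detections(fs, dets)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_intensity_offset_invariance(self, quiet_optics, default_detection):
        fs = make_frameset(quiet_optics, n_beads=20, n_frames=1, seed=22)
        img = fs.localization_frames[0]
        a = detect_beads(img, default_detection)
        b = detect_beads(img + 100.0, default_detection)
        assert len(a) == len(b)
        for (ca, ra), (cb, rb) in zip(
            sorted(a, key=lambda t: t[0]), sorted(b, key=lambda t: t[0])
        ):
            assert ca == pytest.approx(cb, abs=1e-9)
            assert ra == rb

    def test_border_disks_are_discarded(self):
        img = draw_disks((60, 60), [(2.0, 30.0, 6.0), (30.0, 30.0, 6.0)])
        found = detect_beads(img, DetectionParams(radius_min=4, radius_max=9))
        for (row, col), rad in found:
            assert row - rad >= 0 and col - rad >= 0
            assert row + rad <= 59 and col + rad <= 59

    def test_invalid_params_raise(self):
        with pytest.raises(InvalidParameterError):
            DetectionParams(radius_min=8, radius_max=3)
        with pytest.raises(InvalidParameterError):
            DetectionParams(radius_min=3, radius_max=8, sensitivity=0.0)
        with pytest.raises(InvalidParameterError):
            DetectionParams(radius_min=3, radius_max=8, min_separation=0.0)
        with pytest.raises(InvalidParameterError):
            detect_beads(np.zeros((4, 4, 4)), DetectionParams(radius_min=3, radius_max=8))


class TestExtractIntensity:
    def test_uniform_frame_gives_uniform_max(self):
        circles = [((10.0, 10.0), 4.0), ((20.0, 25.0), 3.0)]
        frame = np.full((40, 40), 123.0)
        out = extract_bead_intensity(circles, frame)
        assert [d.max_intensity for d in out] == [123.0, 123.0]
        assert [d.center for d in out] == [c for c, _ in circles]  # order preserved

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        frame = rng.uniform(0, 1000, size=(80, 80))
        for _ in range(100):
            row = rng.uniform(8, 71)
            col = rng.uniform(8, 71)
            rad = rng.uniform(2, 6)
            (det,) = extract_bead_intensity([((row, col), rad)], frame)
            expected = max(
                frame[r, c]
                for r in range(80)
                for c in range(80)
                if (r - row) ** 2 + (c - col) ** 2 <= rad**2
            )
            assert det.max_intensity == expected

    def test_circle_outside_frame_raises(self):
        frame = np.zeros((20, 20))
        with pytest.raises(InvalidParameterError):
            extract_bead_intensity([((100.0, 100.0), 3.0)], frame)


class TestDetectFrameset:
    def test_counts_concatenate_across_frames(self, quiet_optics, default_detection):
        fs = make_frameset(quiet_optics, n_beads=12, n_frames=2, seed=23)
        dets = detect_frameset(fs, default_detection)
        assert len(dets) == len(fs.truth_table)
        per_frame = fs.truth_table.groupby("frame_index").size()
        for f, n in per_frame.items():
            assert sum(d.frame_index == f for d in dets) == n

    def test_stateless_determinism(self, default_optics, default_detection):
        fs = make_frameset(default_optics, n_beads=40, n_frames=2, seed=24)
        a = detect_frameset(fs, default_detection)
        b = detect_frameset(fs, default_detection)
        assert [(d.center, d.radius, d.max_intensity) for d in a] == [
            (d.center, d.radius, d.max_intensity) for d in b
        ]

    def test_channel_mismatch_raises(self, quiet_optics, default_detection):
        fs = make_frameset(quiet_optics, n_beads=5, n_frames=2, seed=25)
        broken = dataclasses.replace(fs)
        broken.fluorescence_frames = fs.fluorescence_frames[:1]
        with pytest.raises(StructuralError):
            detect_frameset(broken, default_detection)

    def test_empty_frameset_yields_empty(self, quiet_optics, default_detection):
        fs = make_frameset(quiet_optics, n_beads=3, n_frames=1, seed=26)
        empty = dataclasses.replace(fs)
        empty.localization_frames = []
        empty.fluorescence_frames = []
        assert detect_frameset(empty, default_detection) == []
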