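import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from digibead import (
    AssayParams,
    OpticsParams,
    render_frames,
    simulate_bead_loading,
    simulate_dilution_series,
)
from digibead.errors import InvalidParameterError, PlacementError


class TestBeadLoading:
    def test_zero_concentration_gives_all_off(self):
        pop = simulate_bead_loading(
            AssayParams(concentration=0.0, capture_coeff=5.0, n_beads=1000, seed=1)
        )
        assert pop.lambda_true == 0.0
        assert not pop.counts.any()
        assert not pop.on_truth.any()

    def test_on_fraction_matches_poisson_closed_form(self):
        lam = 0.5
        n = 10**6
        pop = simulate_bead_loading(
            AssayParams(concentration=lam, capture_coeff=1.0, n_beads=n, seed=2)
        )
        expected = 1.0 - math.exp(-lam)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(pop.on_truth.mean() - expected) < 3 * se

    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.5, 1.0, 3.0])
    def test_poisson_consistency_across_rates(self, lam):
        n = 10**5
        pop = simulate_bead_loading(
            AssayParams(concentration=lam, capture_coeff=1.0, n_beads=n, seed=11)
        )
        expected = 1.0 - math.exp(-lam)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(pop.on_truth.mean() - expected) < 4 * se
        assert np.all(pop.on_truth == (pop.counts >= 1))

    def test_seed_determinism_is_exact(self):
        p = AssayParams(concentration=0.1, capture_coeff=1.0, n_beads=10**5, seed=33)
        a = simulate_bead_loading(p)
        b = simulate_bead_loading(p)
        assert np.array_equal(a.counts, b.counts)
        assert a.counts.mean() == b.counts.mean()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(concentration=-1.0),
            dict(concentration=math.nan),
            dict(capture_coeff=0.0),
            dict(n_beads=0),
            dict(labeling_efficiency=1.5),
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        base = dict(concentration=1.0, capture_coeff=1.0, n_beads=10, labeling_efficiency=1.0)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            AssayParams(**base)


class TestRendering:
    def test_empty_population_renders_pure_background(self, quiet_optics):
        pop = simulate_bead_loading(
            AssayParams(concentration=0.0, capture_coeff=1.0, n_beads=1, seed=3)
        )
        empty = dataclasses.replace(pop, counts=pop.counts[:0], on_truth=pop.on_truth[:0])
        fs = render_frames(empty, quiet_optics, n_frames=2, imaged_fraction=1.0, seed=4)
        assert fs.truth_table.empty
        for frame in fs.fluorescence_frames:
            assert np.all(frame == quiet_optics.background_level)

    def test_noiseless_fluorescence_max_equals_drawn_peak(self, quiet_optics):
        pop = simulate_bead_loading(
            AssayParams(concentration=1.0, capture_coeff=1.0, n_beads=50, seed=5)
        )
        fs = render_frames(pop, quiet_optics, n_frames=1, imaged_fraction=1.0, seed=6)
        assert len(fs.truth_table) == 50
        flu = fs.fluorescence_frames[0]
        for row in fs.truth_table.itertuples():
            rr, cc = np.mgrid[0 : flu.shape[0], 0 : flu.shape[1]]
            mask = (rr - row.row) ** 2 + (cc - row.col) ** 2 <= row.radius**2
            assert flu[mask].max() == pytest.approx(row.peak_intensity, abs=0)

    def test_imaged_fraction_subsamples_binomially(self, default_optics):
        n, frac = 10**4, 0.21
        pop = simulate_bead_loading(
            AssayParams(concentration=1.0, capture_coeff=1.0, n_beads=n, seed=7)
        )
        fs = render_frames(pop, default_optics, n_frames=120, imaged_fraction=frac, seed=8)
        se = math.sqrt(n * frac * (1 - frac))
        assert abs(len(fs.truth_table) - n * frac) < 3 * se
        assert fs.n_frames == 120

    def test_truth_centers_respect_spacing_and_border(self, default_optics):
        fs = render_frames(
            simulate_bead_loading(
                AssayParams(concentration=1.0, capture_coeff=1.0, n_beads=300, seed=9)
            ),
            default_optics,
            n_frames=4,
            imaged_fraction=1.0,
            seed=10,
        )
        h, w = default_optics.image_shape
        t = fs.truth_table
        assert np.all(t.row >= t.radius) and np.all(t.row <= h - 1 - t.radius)
        assert np.all(t.col >= t.radius) and np.all(t.col <= w - 1 - t.radius)
        for _, grp in t.groupby("frame_index"):
            pos = grp[["row", "col"]].to_numpy()
            rad = grp["radius"].to_numpy()
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    d = math.hypot(*(pos[i] - pos[j]))
                    assert d >= 2.2 * max(rad[i], rad[j]) - 1e-9

    def test_render_determinism(self, default_optics):
        pop = simulate_bead_loading(
            AssayParams(concentration=1.0, capture_coeff=1.0, n_beads=100, seed=12)
        )
        a = render_frames(pop, default_optics, n_frames=3, imaged_fraction=0.5, seed=13)
        b = render_frames(pop, default_optics, n_frames=3, imaged_fraction=0.5, seed=13)
        for fa, fb in zip(a.fluorescence_frames, b.fluorescence_frames):
            assert np.array_equal(fa, fb)
        pd.testing.assert_frame_equal(a.truth_table, b.truth_table)

    def test_overpacked_frame_raises_placement_error(self):
        optics = OpticsParams(image_shape=(48, 48), bead_radius_px=6.0, radius_jitter=0.0)
        pop = simulate_bead_loading(
            AssayParams(concentration=1.0, capture_coeff=1.0, n_beads=200, seed=14)
        )
        with pytest.raises(PlacementError, match="frame 0"):
            render_frames(pop, optics, n_frames=1, imaged_fraction=1.0, seed=15)

    def test_invalid_render_arguments(self, default_optics):
        pop = simulate_bead_loading(
            AssayParams(concentration=1.0, capture_coeff=1.0, n_beads=5, seed=16)
        )
        with pytest.raises(InvalidParameterError):
            render_frames(pop, default_optics, n_frames=0, imaged_fraction=0.5, seed=1)
        with pytest.raises(InvalidParameterError):
            render_frames(pop, default_optics, n_frames=1, imaged_fraction=0.0, seed=1)

    def test_nonseparable_optics_rejected_unless_opted_in(self):
        with pytest.raises(InvalidParameterError):
            OpticsParams(on_intensity_mu=math.log(8500.0))
        OpticsParams(on_intensity_mu=math.log(8500.0), check_separable=False)


class TestDilutionSeries:
    BASE = AssayParams(concentration=0.0, capture_coeff=0.5, n_beads=300, seed=0)
    SMALL = OpticsParams(image_shape=(128, 128))

    def test_cell_and_manifest_counts(self):
        concs = [0.0, 0.1, 0.3, 1.0, 3.0, 10.0]
        conds, manifest = simulate_dilution_series(
            concs, self.BASE, self.SMALL, replicates=3, seed=1, n_frames=2, imaged_fraction=0.5
        )
        assert len(conds) == 18
        assert len(manifest) == 18
        assert sorted(set(manifest.concentration)) == concs

    def test_blank_only_series_is_all_off(self):
        conds, _ = simulate_dilution_series(
            [0.0], self.BASE, self.SMALL, replicates=3, seed=2, n_frames=2, imaged_fraction=0.5
        )
        assert len(conds) == 3
        for c in conds:
            assert not c.frameset.truth_table.on.any()

    def test_master_seed_reproducibility(self):
        kwargs = dict(replicates=2, seed=3, n_frames=2, imaged_fraction=0.5)
        a_conds, a_man = simulate_dilution_series([0.0, 1.0], self.BASE, self.SMALL, **kwargs)
        b_conds, b_man = simulate_dilution_series([0.0, 1.0], self.BASE, self.SMALL, **kwargs)
        pd.testing.assert_frame_equal(a_man, b_man)
        for ca, cb in zip(a_conds, b_conds):
            for fa, fb in zip(ca.frameset.fluorescence_frames, cb.frameset.fluorescence_frames):
                assert np.array_equal(fa, fb)

    def test_bad_inputs_raise(self):
        with pytest.raises(InvalidParameterError):
            simulate_dilution_series([], self.BASE, self.SMALL)
        with pytest.raises(InvalidParameterError):
            simulate_dilution_series([1.0, 0.0], self.BASE, self.SMALL)
        with pytest.raises(InvalidParameterError):
            simulate_dilution_series([-1.0, 0.0], self.BASE, self.SMALL)
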