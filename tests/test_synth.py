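import numpy as np
import pytest

from nucleomech import synth
from nucleomech.errors import ValidationError

from conftest import polygon_arc_length


class TestBrownianTracks:
    def test_zero_diffusion_is_stationary(self):
        df, _ = synth.simulate_brownian_tracks(0.0, n_particles=3, n_frames=10, dt=0.01, seed=0)
        for _, grp in df.groupby("particle_id"):
            assert grp["x_um"].nunique() == 1
            assert grp["y_um"].nunique() == 1

    def test_step_variance_matches_2_D_dt(self):
        # sample-variance oracle on the generated steps, n = 49,900
        D, dt = 0.1, 0.01
        df, _ = synth.simulate_brownian_tracks(D, n_particles=100, n_frames=500, dt=dt, seed=1)
        steps = []
        for _, grp in df.groupby("particle_id"):
            steps.append(np.diff(grp["x_um"].to_numpy()))
            steps.append(np.diff(grp["y_um"].to_numpy()))
        var = np.concatenate(steps).var()
        assert var == pytest.approx(2 * D * dt, rel=0.05)

    def test_default_regime_500_frames(self):
        # 100 fps for 5 s
        df, gt = synth.simulate_brownian_tracks(0.1, n_particles=2, n_frames=500, dt=0.01, seed=0)
        assert (df.groupby("particle_id").size() == 500).all()
        assert gt["n_frames"] == 500

    def test_bit_identical_regeneration(self):
        a, _ = synth.simulate_brownian_tracks(0.1, 5, 50, 0.01, 0.02, seed=42)
        b, _ = synth.simulate_brownian_tracks(0.1, 5, 50, 0.01, 0.02, seed=42)
        assert a.equals(b)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValidationError):
            synth.simulate_brownian_tracks(-0.1, 5, 50, 0.01)
        with pytest.raises(ValidationError):
            synth.simulate_brownian_tracks(0.1, 5, 1, 0.01)


class TestParticleMovie:
    def test_static_particle_centroid_exact(self):
        import pandas as pd

        tracks = pd.DataFrame(
            {"particle_id": [0], "frame": [0], "x_um": [3.21], "y_um": [2.87]}
        )
        movie = synth.render_particle_movie(
            tracks, image_shape=(64, 64), pixel_size_um=0.1, background=0.0, noise_sd=0.0
        )
        frame = movie.frame(0)
        yy, xx = np.mgrid[0:64, 0:64]
        cx = (xx * frame).sum() / frame.sum()
        cy = (yy * frame).sum() / frame.sum()
        assert cx == pytest.approx(32.1, abs=1e-6)
        assert cy == pytest.approx(28.7, abs=1e-6)

    def test_two_particles_two_maxima(self):
        import pandas as pd
        from scipy.ndimage import maximum_filter

        tracks = pd.DataFrame(
            {"particle_id": [0, 1], "frame": [0, 0], "x_um": [2.0, 4.0], "y_um": [3.0, 3.0]}
        )
        movie = synth.render_particle_movie(
            tracks, image_shape=(64, 64), pixel_size_um=0.1, background=0.0, noise_sd=0.0
        )
        frame = movie.frame(0)
        peaks = (frame == maximum_filter(frame, size=5)) & (frame > 1.0)
        assert peaks.sum() == 2

    def test_out_of_frame_clipped_with_warning(self, caplog):
        import pandas as pd

        tracks = pd.DataFrame(
            {"particle_id": [0], "frame": [0], "x_um": [99.0], "y_um": [99.0]}
        )
        with caplog.at_level("WARNING"):
            synth.render_particle_movie(tracks, image_shape=(32, 32), pixel_size_um=0.1)
        assert any("clipped" in r.message for r in caplog.records)


class TestSpectralStack:
    def test_donor_channel_dominates_window(self):
        stack, _ = synth.synth_spectral_stack(200.0, 100.0, noise_sd=0.0, shape=(4, 4))
        wl = np.asarray(stack.channel_wavelengths_nm)
        window = (wl >= 470) & (wl <= 490)
        i480 = int(np.argwhere(wl == 480)[0, 0])
        spectrum = stack.pixels[:, 0, 0]
        assert spectrum[i480] == spectrum[window].max()

    def test_peak_outside_range_rejected(self):
        with pytest.raises(ValidationError):
            synth.synth_spectral_stack(1.0, 1.0, donor_peak_nm=650.0)

    def test_bit_identical_regeneration(self):
        a, _ = synth.synth_spectral_stack(150.0, 100.0, noise_sd=5.0, seed=9)
        b, _ = synth.synth_spectral_stack(150.0, 100.0, noise_sd=5.0, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestPhotonDecay:
    def test_wide_window_mean_approaches_tau(self):
        tau = 2.5
        edges, counts, _ = synth.synth_photon_decay(tau, 200_000, window_ns=100.0, n_bins=4096, seed=0)
        mid = 0.5 * (edges[:-1] + edges[1:])
        mean = np.average(mid, weights=counts)
        assert mean == pytest.approx(tau, rel=0.02)

    def test_single_photon_histogram(self):
        _, counts, _ = synth.synth_photon_decay(2.5, 1, 12.5, 64, seed=0)
        assert counts.sum() == 1

    def test_validation(self):
        with pytest.raises(ValidationError):
            synth.synth_photon_decay(-1.0, 100, 12.5, 64)
        with pytest.raises(ValidationError):
            synth.synth_photon_decay(2.5, 0, 12.5, 64)
        with pytest.raises(ValidationError):
            synth.synth_photon_decay(2.5, 100, 0.1, 64)


class TestSynthNucleus:
    def test_convex_truth_is_one(self):
        _, _, _, gt = synth.synth_nucleus(semi_axes_um=(6.0, 6.0), invaginations=[])
        assert gt["eop"] == pytest.approx(1.0, abs=1e-6)

    def test_slit_adds_two_walls(self):
        # closed-form: (P + 2 d) / hull perimeter, checked via exact polygon oracle
        depth, width = 2.0, 0.3
        _, _, region, gt = synth.synth_nucleus(
            semi_axes_um=(8.0, 5.0), invaginations=[(0.0, depth, width)]
        )
        oracle = polygon_arc_length(np.asarray(region.exterior.coords)[:-1])
        hull_oracle = polygon_arc_length(
            np.asarray(region.convex_hull.exterior.coords)[:-1]
        )
        assert gt["eop"] == pytest.approx(oracle / hull_oracle, rel=1e-12)
        assert gt["eop"] == pytest.approx(gt["eop_analytic"], rel=0.01)

    def test_overlapping_invaginations_rejected(self):
        with pytest.raises(ValidationError):
            synth.synth_nucleus(invaginations=[(0.0, 2.0, 0.5), (1.0, 2.0, 0.5)])

    def test_mask_and_skeleton_shapes_agree(self):
        mask, skel, _, _ = synth.synth_nucleus()
        assert mask.labels.shape == skel.shape
        assert mask.labels.max() == 1
        assert skel.any()


class TestPolarizedCells:
    def test_front_fraction_one_puts_all_top_pixels_front(self):
        cells, _ = synth.synth_polarized_cell(1.0, n_cells=5, randomize_orientation=False, seed=0)
        for cell in cells:
            mask = cell["mask"].labels > 0
            sig = cell["signal"]
            yy, xx = np.nonzero(mask)
            vals = sig[yy, xx]
            n_top = int(np.ceil(0.2 * len(vals)))
            order = np.argsort(-vals, kind="stable")[:n_top]
            cx = xx.mean()
            assert np.all(xx[order] > cx - 1)  # front half (+x), unrotated

    def test_golgi_on_front_side(self):
        cells, _ = synth.synth_polarized_cell(0.7, n_cells=10, seed=3)
        for cell in cells:
            mask = cell["mask"].labels > 0
            yy, xx = np.nonzero(mask)
            cx, cy = xx.mean(), yy.mean()
            gx, gy = cell["golgi_centroid"]
            dot = (gx - cx) * np.cos(cell["angle_rad"]) + (gy - cy) * np.sin(cell["angle_rad"])
            assert dot > 0

    def test_invalid_fraction(self):
        with pytest.raises(ValidationError):
            synth.synth_polarized_cell(1.5)


class TestCellImage:
    def test_true_nc_ratio_recorded(self):
        _, _, _, gt = synth.synth_cell_image(nuc_intensity=100.0, cyto_intensity=50.0, seed=0)
        assert gt["nc_ratio"] == 2.0

    def test_blob_count_by_construction(self):
        stack, _, cell, gt = synth.synth_cell_image(n_fa_blobs=12, seed=1)
        assert len(gt["blob_centres_px"]) == 12

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValidationError):
            synth.synth_cell_image(n_fa_blobs=5000, image_shape=(64, 64), seed=0)


class TestCellTrajectories:
    def test_default_grid_109_samples(self):
        df, gt = synth.simulate_cell_trajectories(n_cells=3, seed=0)
        assert gt["n_samples"] == 109
        assert (df.groupby("cell_id").size() == 109).all()

    def test_zero_rotation_is_straight(self):
        df, _ = synth.simulate_cell_trajectories(0.5, 0.0, n_cells=2, seed=0)
        for _, grp in df.groupby("cell_id"):
            dx = np.diff(grp["x_um"])
            dy = np.diff(grp["y_um"])
            headings = np.arctan2(dy, dx)
            assert np.allclose(headings, headings[0])

    def test_zero_speed_is_stationary(self):
        df, _ = synth.simulate_cell_trajectories(0.0, 0.1, n_cells=2, seed=0)
        for _, grp in df.groupby("cell_id"):
            assert grp["x_um"].nunique() == 1
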