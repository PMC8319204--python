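import numpy as np
import pytest

from mfi3d.bead3d import (
    CircleFitPatch,
    CircleFitResult,
    RadiusCalibration,
    SingularFitError,
    align_profiles,
    build_radius_calibration,
    detect_beads,
    fit_circle_weighted,
    infer_bead_z,
    link_tracks,
    measure_bead_radius,
    predict_z_precision,
    preprocess_video,
    select_min_std_combination,
)
from mfi3d.optics_forward import Bead, SceneSpec, render_multifocal_frame
from tests.conftest import render_bead_sweep


def brute_force_circle_fit(patch):
    """Independent oracle: explicit normal-equations solve of the weighted
    linearized circle system (same weighting convention, different path)."""
    w = patch.intensity**2
    a_mat = np.column_stack(
        [2 * patch.x, 2 * patch.y, np.ones_like(patch.x)]
    ) * w[:, None]
    b_vec = (patch.x**2 + patch.y**2) * w
    xc, yc, b = np.linalg.solve(a_mat.T @ a_mat, a_mat.T @ b_vec)
    return xc, yc, b


class TestPreprocessVideo:
    def _frames(self, optics, psf, moving=True):
        pitch = optics.pixel_pitch_sample
        frames = []
        for t in range(5):
            objs = [Bead(center=(8 * pitch, 8 * pitch, 1.0))]  # static
            if moving:
                objs.append(Bead(center=((20 + 3 * t) * pitch, 20 * pitch, 1.0)))
            frames.append(
                render_multifocal_frame(
                    SceneSpec(objects=objs, read_noise_frac=0.0), optics, psf
                )
            )
        return frames

    def test_static_scene_removed(self, optics, psf):
        frames = self._frames(optics, psf, moving=False)
        projection, _ = preprocess_video(frames, subtract_static=True)
        assert projection.max() < 1e-9

    def test_moving_bead_retained_static_removed(self, optics, psf):
        frames = self._frames(optics, psf, moving=True)
        projection, _ = preprocess_video(frames, subtract_static=True)
        assert projection[0][8, 8] < 0.35 * projection[0][20, 20]

    def test_max_projection_equals_brightest_plane(self, optics, psf):
        frames = self._frames(optics, psf, moving=False)
        projection, _ = preprocess_video(frames)
        stacked = frames[0].planes
        np.testing.assert_array_equal(projection[0], stacked.max(axis=0))

    def test_subtraction_needs_two_frames(self, optics, psf):
        frames = self._frames(optics, psf)[:1]
        with pytest.raises(ValueError):
            preprocess_video(frames, subtract_static=True)


class TestDetectBeads:
    def test_blank_image_empty(self):
        assert detect_beads(np.zeros((64, 64)), threshold=1.0).size == 0

    def test_single_bead_subpixel(self, optics, psf):
        pitch = optics.pixel_pitch_sample
        true = (20.3, 19.6)
        scene = SceneSpec(
            objects=[Bead(center=(true[0] * pitch, true[1] * pitch, 0.5))],
            read_noise_frac=0.005,
            seed=1,
        )
        frame = render_multifocal_frame(scene, optics, psf)
        projection = frame.planes.max(axis=0)
        centers = detect_beads(projection, diameter_px=10, threshold=0.5)
        assert len(centers) == 1
        assert np.hypot(*(centers[0] - true)) < 0.3

    def test_two_separated_beads(self, optics, psf):
        pitch = optics.pixel_pitch_sample
        scene = SceneSpec(
            objects=[
                Bead(center=(8 * pitch, 8 * pitch, 0.5)),
                Bead(center=(32 * pitch, 32 * pitch, 0.5)),
            ],
            read_noise_frac=0.0,
        )
        frame = render_multifocal_frame(scene, optics, psf)
        centers = detect_beads(frame.planes.max(axis=0), threshold=0.5)
        assert len(centers) == 2

    def test_diameter_validation(self):
        with pytest.raises(ValueError):
            detect_beads(np.zeros((8, 8)), diameter_px=2)


class TestFitCircleWeighted:
    def _ring(self, n=8, center=(10.0, 10.0), radius=5.0):
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        x = center[0] + radius * np.cos(theta)
        y = center[1] + radius * np.sin(theta)
        return x, y

    def test_exact_circle_uniform_weights(self):
        x, y = self._ring()
        patch = CircleFitPatch(x, y, np.ones_like(x))
        res = fit_circle_weighted(patch)
        assert res.center == pytest.approx((10.0, 10.0), abs=1e-9)
        assert res.radius == pytest.approx(5.0, abs=1e-9)

    def test_exact_circle_weight_invariant(self):
        x, y = self._ring()
        w = np.linspace(1.0, 9.0, len(x))
        res_u = fit_circle_weighted(CircleFitPatch(x, y, np.ones_like(x)))
        res_w = fit_circle_weighted(CircleFitPatch(x, y, w))
        assert res_w.center == pytest.approx(res_u.center, abs=1e-9)
        assert res_w.radius == pytest.approx(res_u.radius, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_noisy_rings(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(12, 40)
        theta = rng.uniform(0, 2 * np.pi, n)
        radius = rng.uniform(3, 8)
        cx, cy = rng.uniform(5, 25, 2)
        x = cx + radius * np.cos(theta) + rng.normal(0, 0.1, n)
        y = cy + radius * np.sin(theta) + rng.normal(0, 0.1, n)
        intensity = rng.uniform(0.5, 3.0, n)
        patch = CircleFitPatch(x, y, intensity)
        res = fit_circle_weighted(patch)
        xc, yc, b = brute_force_circle_fit(patch)
        assert res.center[0] == pytest.approx(xc, abs=1e-9)
        assert res.center[1] == pytest.approx(yc, abs=1e-9)
        assert res.b == pytest.approx(b, abs=1e-9)

    def test_collinear_raises(self):
        x = np.linspace(0, 10, 8)
        y = 2.0 * x + 1.0
        with pytest.raises(SingularFitError):
            fit_circle_weighted(CircleFitPatch(x, y, np.ones_like(x)))

    def test_negative_radius_flagged_invalid(self):
        # weighted mean of rho^2 can only be negative through b; construct a
        # degenerate-ish patch whose solution has x_c^2+y_c^2+b < 0 by
        # checking the flag path directly
        res = CircleFitResult((0.0, 0.0), -1.0, float("nan"), 0.9, valid=False)
        inference_input = [res, res, res, res]
        cal = RadiusCalibration(
            np.arange(-1.0, 1.05, 0.1),
            np.ones((4, 21)),
            np.zeros((4, 21)),
            np.zeros((4, 21)),
        )
        out = infer_bead_z(inference_input, cal)
        assert out.excluded

    def test_minimum_pixel_count(self):
        with pytest.raises(ValueError):
            CircleFitPatch(np.arange(3.0), np.arange(3.0), np.ones(3))


class TestRadiusCalibration:
    def test_alignment_recovers_injected_offset(self):
        z = np.arange(-5.0, 5.05, 0.1)
        curve = 1.5 + 0.1 * z**2
        profiles = np.stack(
            [
                np.tile(curve, (4, 1)),
                np.tile(1.5 + 0.1 * (z - 1.0) ** 2, (4, 1)),
            ]
        )
        _, offsets = align_profiles(profiles, z)
        assert offsets[1] == pytest.approx(1.0, abs=0.05)

    def test_single_noiseless_bead(self):
        z = np.arange(-3.0, 3.05, 0.1)
        curve = np.tile(2.0 + 0.05 * z**2, (4, 1))
        cal = build_radius_calibration(curve[None], z, smooth_window_um=0.0)
        np.testing.assert_allclose(cal.radius, curve, atol=1e-12)
        np.testing.assert_allclose(cal.sigma_r, 0.0)

    def test_sigma_z_structure(self, bead_calibration, coarse_z_grid):
        """Error propagation: sigma_z diverges at each plane's focus (flat
        curve) and is best where |dR/dz| is largest."""
        cal = bead_calibration
        for k, focus in enumerate([0.0, 2.9, 5.9, 8.8]):
            i_focus = int(np.argmin(np.abs(cal.z_grid - focus)))
            off_focus = np.abs(cal.z_grid - focus) > 3.0
            near = cal.sigma_z[k, max(i_focus - 2, 0) : i_focus + 3]
            assert np.nanmax(near) > 2.0 * np.nanmedian(cal.sigma_z[k][off_focus])

    def test_combined_precision_monotone_in_planes(self, bead_calibration):
        _, mean1 = predict_z_precision(bead_calibration, [0])
        _, mean12 = predict_z_precision(bead_calibration, [0, 1])
        _, mean_all = predict_z_precision(bead_calibration)
        assert mean_all <= mean12 <= mean1
        comb1, _ = predict_z_precision(bead_calibration, [0])
        comb_all, _ = predict_z_precision(bead_calibration)
        assert np.all(comb_all <= comb1 + 1e-12)

    def test_single_plane_combined_identity(self, bead_calibration):
        comb, _ = predict_z_precision(bead_calibration, [2])
        np.testing.assert_array_equal(comb, bead_calibration.sigma_z[2])

    def test_empty_plane_subset_raises(self, bead_calibration):
        with pytest.raises(ValueError):
            predict_z_precision(bead_calibration, [])

    def test_json_round_trip(self, bead_calibration, tmp_path):
        path = tmp_path / "cal.json"
        bead_calibration.to_json(path)
        loaded = RadiusCalibration.from_json(path)
        np.testing.assert_allclose(loaded.radius, bead_calibration.radius)
        np.testing.assert_allclose(loaded.sigma_z, bead_calibration.sigma_z)


class TestInferBeadZ:
    def test_round_trip_at_known_z(self, optics, psf, bead_calibration, coarse_z_grid):
        _, fits = render_bead_sweep(optics, psf, np.array([3.0]), seed=55)
        inference = infer_bead_z(fits[0], bead_calibration)
        assert not inference.excluded
        sigma = max(
            min(
                bead_calibration.sigma_z_at(k, 3.0)
                for k in range(4)
            ),
            0.05,
        )
        assert abs(inference.z - 3.0) <= max(2.0 * sigma, 0.3)

    def test_insufficient_planes_excluded(self, bead_calibration):
        good = CircleFitResult((0, 0), 4.0, 2.0, 0.95)
        bad = CircleFitResult((0, 0), 4.0, 2.0, 0.5)
        out = infer_bead_z([good, bad, bad, bad], bead_calibration)
        assert out.excluded
        assert out.reason == "insufficient valid planes"

    def test_single_plane_ambiguous(self, bead_calibration):
        good = CircleFitResult((0, 0), 4.0, 2.5, 0.95)
        out = infer_bead_z([good, None, None, None], bead_calibration)
        assert out.excluded
        assert out.ambiguous
        assert len(out.candidates.get(0, [])) == 2

    def test_never_z_with_fewer_than_two_planes(self, bead_calibration):
        good = CircleFitResult((0, 0), 4.0, 2.5, 0.95)
        out = infer_bead_z([good, None, None, None], bead_calibration)
        assert np.isnan(out.z)

    def test_min_std_combination_helper(self):
        candidates = {0: [1.0, 5.0], 1: [1.05, -3.0]}
        chosen, z, _, _ = select_min_std_combination(candidates, lambda p, z: 1.0)
        assert chosen == {0: 1.0, 1: 1.05}
        assert z in (1.0, 1.05)


class TestLinkTracks:
    def test_single_drifting_bead(self):
        positions = [np.array([[0.1 * t, 0.0, 0.0]]) for t in range(20)]
        tracks = link_tracks(positions)
        assert len(tracks) == 1
        assert len(tracks[0]) == 20

    def test_jump_over_limit_splits_track(self):
        positions = [
            np.array([[0.0, 0.0, 0.0]]),
            np.array([[1.6, 0.0, 0.0]]),
            np.array([[1.7, 0.0, 0.0]]),
        ]
        tracks = link_tracks(positions, max_dist=1.5)
        assert len(tracks) == 2

    def test_exact_threshold_forbidden(self):
        positions = [np.array([[0.0, 0.0, 0.0]]), np.array([[1.5, 0.0, 0.0]])]
        assert len(link_tracks(positions, max_dist=1.5)) == 2

    def test_well_separated_beads_never_swap(self):
        rng = np.random.default_rng(4)
        a = np.cumsum(rng.normal(0, 0.1, (50, 3)), axis=0)
        b = np.cumsum(rng.normal(0, 0.1, (50, 3)), axis=0) + [5.0, 0.0, 0.0]
        positions = [np.stack([a[t], b[t]]) for t in range(50)]
        tracks = link_tracks(positions)
        assert len(tracks) == 2
        for tr in tracks:
            start = tr.positions[0]
            ref = a if np.linalg.norm(start - a[0]) < 1e-9 else b
            np.testing.assert_allclose(tr.positions, ref)

    def test_time_strictly_increasing(self):
        positions = [np.array([[0.0, 0.0, 0.0]])] * 10
        for tr in link_tracks(positions):
            assert np.all(np.diff(tr.frames) > 0)


class TestRoundTripRegression:
    def test_slope_and_residuals(self, optics, psf, bead_calibration, coarse_z_grid):
        """Inferred vs true z across the calibrated depth: unity slope and
        residual sd bounded by the predicted precision (coarse-grid variant
        of the acceptance protocol)."""
        z_true, z_inf, sigma_pred = [], [], []
        for seed in (200, 201):
            _, fits = render_bead_sweep(optics, psf, coarse_z_grid, seed)
            for j, z in enumerate(coarse_z_grid):
                inference = infer_bead_z(fits[j], bead_calibration)
                if inference.excluded:
                    continue
                z_true.append(z)
                z_inf.append(inference.z)
                sigma_pred.append(inference.sigma_z)
        z_true = np.asarray(z_true)
        z_inf = np.asarray(z_inf)
        assert len(z_true) > 0.9 * 2 * len(coarse_z_grid)
        slope, intercept = np.polyfit(z_true, z_inf, 1)
        assert slope == pytest.approx(1.0, abs=0.05)
        ss_res = np.sum((z_inf - (slope * z_true + intercept)) ** 2)
        ss_tot = np.sum((z_inf - z_inf.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.99
        resid = z_inf - z_true
        finite = np.isfinite(sigma_pred)
        assert resid.std() <= 1.5 * max(np.nanmean(np.asarray(sigma_pred)[finite]), 0.15)
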