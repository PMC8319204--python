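import numpy as np
import pytest

from mfi3d.flagellum3d import (
    NoFlagellumError,
    build_width_calibration,
    extract_centerline_2d,
    fit_gaussian_profiles,
    infer_flagellar_z,
    infer_z_from_intensity,
    measure_width_profile,
    reconstruct_video,
    select_sharpest_plane,
    smooth_arclength,
    widths_on_grid,
)
from mfi3d.frame import MultifocalFrame
from mfi3d.optics_forward import (
    DEFAULT_ARC_PITCH_UM,
    BeatWaveformSpec,
    Filament,
    SceneSpec,
    render_multifocal_frame,
    simulate_flagellar_beat,
)

OFFSETS = np.array([0.0, 2.9, 5.9, 8.8])
PITCH = 11.0 / 32.0


def straight_filament_points(length=40.0, z=0.0, origin=(5.0, 20.0)):
    s = np.arange(0.0, length, 0.1)
    return np.column_stack(
        [origin[0] + s, np.full_like(s, origin[1]), np.full_like(s, z)]
    )


def render_filament(points, optics, psf, seed=0, noise=0.02):
    scene = SceneSpec(
        objects=[Filament(points=points)], read_noise_frac=noise, seed=seed
    )
    return render_multifocal_frame(scene, optics, psf)


class TestSelectSharpestPlane:
    def test_in_focus_plane_selected(self, flagellum_optics, psf):
        points = straight_filament_points(z=OFFSETS[1])
        frame = render_filament(points, flagellum_optics, psf)
        assert select_sharpest_plane(frame) == 1

    def test_tie_breaks_to_first(self):
        planes = np.tile(np.random.default_rng(0).uniform(0, 1, (32, 32)), (4, 1, 1))
        frame = MultifocalFrame(planes, OFFSETS, PITCH)
        assert select_sharpest_plane(frame) == 0

    def test_offset_invariance(self, flagellum_optics, psf):
        points = straight_filament_points(z=OFFSETS[2])
        frame = render_filament(points, flagellum_optics, psf)
        shifted = frame.copy()
        shifted.planes[0] += 100.0
        assert select_sharpest_plane(shifted) == select_sharpest_plane(frame)


class TestExtractCenterline:
    def test_straight_filament_geometry(self, flagellum_optics, psf):
        points = straight_filament_points(length=40.0, z=1.0)
        frame = render_filament(points, flagellum_optics, psf)
        trace = extract_centerline_2d(frame.planes[0], PITCH)
        assert trace.length == pytest.approx(40.0, abs=0.5)
        # max perpendicular deviation from the true line y = 20 µm
        dev_px = np.abs(trace.points_px[:, 1] - 20.0 / PITCH)
        assert dev_px.max() < 0.3

    def test_arc_curvature_recovered(self, flagellum_optics, psf):
        spec = BeatWaveformSpec(c0=0.05, c1=0.0, c2=0.0, length=40.0)
        pts = simulate_flagellar_beat(spec, 1, origin=(8.0, 12.0, 1.0))[0]
        frame = render_filament(pts, flagellum_optics, psf)
        trace = extract_centerline_2d(frame.planes[0], PITCH)
        xy = trace.points_px * PITCH
        from mfi3d.beat_metrics import taubin_circle_fit

        interior = xy[5:-5]
        _, _, radius = taubin_circle_fit(interior)
        assert 1.0 / radius == pytest.approx(0.05, abs=0.005)

    def test_blank_image_raises(self):
        with pytest.raises(NoFlagellumError):
            extract_centerline_2d(np.zeros((64, 64)), PITCH)

    def test_arc_length_strictly_increasing(self, flagellum_optics, psf):
        frame = render_filament(
            straight_filament_points(), flagellum_optics, psf
        )
        trace = extract_centerline_2d(frame.planes[0], PITCH)
        assert trace.s[0] == 0.0
        assert np.all(np.diff(trace.s) > 0)


class TestMeasureWidthProfile:
    def test_known_gaussian_cross_section(self):
        """Synthetic ridge with exact Gaussian cross-section sd 1.0 µm."""
        h, w = 64, 128
        yy = np.arange(h)[:, None]
        sigma_px = 1.0 / PITCH
        img = 100.0 * np.exp(-((yy - 32.0) ** 2) / (2 * sigma_px**2))
        img = np.tile(img, (1, w))
        planes = np.stack([img] * 4)
        frame = MultifocalFrame(planes, OFFSETS, PITCH)
        s = np.arange(0.0, 30.0, DEFAULT_ARC_PITCH_UM)
        from mfi3d.flagellum3d import FlagellumTrace2D

        pts = np.column_stack([10 + s / PITCH, np.full_like(s, 32.0)])
        trace = FlagellumTrace2D(pts, s, PITCH)
        measure_width_profile(frame, trace)
        good = trace.width_flags[0]
        assert good.mean() > 0.9
        assert np.nanmedian(trace.widths[0][good]) == pytest.approx(1.0, abs=0.05)

    def test_defocused_plane_wider(self, flagellum_optics, psf):
        points = straight_filament_points(z=OFFSETS[0])
        frame = render_filament(points, flagellum_optics, psf, noise=0.0)
        trace = extract_centerline_2d(frame.planes[0], PITCH)
        measure_width_profile(frame, trace)
        interior = slice(10, -10)
        w_focus = np.nanmedian(trace.widths[0][interior])
        for k in (1, 2, 3):
            assert np.nanmedian(trace.widths[k][interior]) > w_focus

    def test_uniform_background_flagged(self):
        planes = np.full((4, 64, 64), 10.0)
        planes += np.random.default_rng(0).normal(0, 0.1, planes.shape)
        frame = MultifocalFrame(planes, OFFSETS, PITCH)
        s = np.arange(0.0, 10.0, DEFAULT_ARC_PITCH_UM)
        from mfi3d.flagellum3d import FlagellumTrace2D

        pts = np.column_stack([20 + s / PITCH, np.full_like(s, 32.0)])
        trace = FlagellumTrace2D(pts, s, PITCH)
        measure_width_profile(frame, trace)
        assert trace.width_flags.mean() < 0.2


class TestGaussianProfileFitter:
    def test_exact_profiles(self):
        x = np.linspace(-10, 10, 41)
        rng = np.random.default_rng(1)
        amps = rng.uniform(5, 50, 20)
        mus = rng.uniform(-3, 3, 20)
        sigmas = rng.uniform(1.0, 4.0, 20)
        offs = rng.uniform(0, 5, 20)
        profiles = (
            amps[:, None]
            * np.exp(-((x[None] - mus[:, None]) ** 2) / (2 * sigmas[:, None] ** 2))
            + offs[:, None]
        )
        params, flags = fit_gaussian_profiles(profiles, x)
        assert flags.all()
        np.testing.assert_allclose(params[:, 1], mus, atol=1e-6)
        np.testing.assert_allclose(params[:, 2], sigmas, rtol=1e-6)


class TestWidthCalibration:
    def test_single_cell_map_minimum_at_focus(self, width_map):
        i_mid = len(width_map.s_grid) // 2
        for k in range(4):
            row = width_map.width[k, i_mid]
            finite = np.isfinite(row)
            dz_at_min = width_map.dz_grid[finite][np.argmin(row[finite])]
            assert abs(dz_at_min) < 0.8

    def test_two_identical_cells_average_to_same(self, width_map, flagellum_optics):
        # averaging a cell with itself must reproduce the single-cell map
        s_grid = width_map.s_grid
        dz = width_map.dz_grid
        nz = 40
        piezo = np.linspace(-2, 9, nz)
        rng = np.random.default_rng(0)
        cell = np.abs(rng.normal(1.0, 0.2, (nz, 4, len(s_grid))))
        m1 = build_width_calibration([cell], piezo, OFFSETS, s_grid)
        m2 = build_width_calibration([cell, cell], piezo, OFFSETS, s_grid)
        np.testing.assert_allclose(m1.width, m2.width, equal_nan=True)

    def test_bad_shape_rejected(self, width_map):
        with pytest.raises(ValueError):
            build_width_calibration(
                [np.zeros((5, 4, 3))],
                np.linspace(0, 1, 5),
                OFFSETS,
                width_map.s_grid,
            )


class TestInferFlagellarZ:
    def test_immotile_flagellum_flat_profile(self, flagellum_optics, psf, width_map):
        cal_spec = BeatWaveformSpec(c0=0.02, c1=0.05, c2=0.006, f0=25.0)
        base = simulate_flagellar_beat(cal_spec, 1, origin=(6.0, 18.0, 0.0))[0]
        pts = base.copy()
        pts[:, 2] = 2.0
        frame = render_filament(pts, flagellum_optics, psf, seed=77)
        trace = extract_centerline_2d(
            frame.planes[select_sharpest_plane(frame)],
            PITCH,
            head_hint=(base[0, 0] / PITCH, base[0, 1] / PITCH),
        )
        measure_width_profile(frame, trace)
        z, ok = infer_flagellar_z(trace, width_map, OFFSETS)
        z = smooth_arclength(z)
        distal = (trace.s > 10) & np.isfinite(z)
        assert distal.sum() > 50
        assert np.nanmedian(z[distal]) == pytest.approx(2.0, abs=0.4)
        assert np.nanstd(z[distal]) < 0.5

    def test_sweep_regression_slope_unity(self, flagellum_optics, psf, width_map):
        cal_spec = BeatWaveformSpec(c0=0.02, c1=0.05, c2=0.006, f0=25.0)
        base = simulate_flagellar_beat(cal_spec, 1, origin=(6.0, 18.0, 0.0))[0]
        z_true, z_est = [], []
        for j, zp in enumerate(np.arange(0.5, 8.6, 0.8)):
            pts = base.copy()
            pts[:, 2] = zp
            frame = render_filament(pts, flagellum_optics, psf, seed=900 + j)
            trace = extract_centerline_2d(
                frame.planes[select_sharpest_plane(frame)],
                PITCH,
                head_hint=(base[0, 0] / PITCH, base[0, 1] / PITCH),
            )
            measure_width_profile(frame, trace)
            z, ok = infer_flagellar_z(trace, width_map, OFFSETS)
            z = smooth_arclength(z)
            distal = (trace.s > 10) & np.isfinite(z)
            z_true.append(zp)
            z_est.append(np.nanmedian(z[distal]))
        slope = np.polyfit(z_true, z_est, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_width_at_map_minimum_single_candidate(self, width_map):
        from mfi3d.flagellum3d import _width_candidates

        i_mid = len(width_map.s_grid) // 2
        curve = width_map.width[0, i_mid]
        finite = np.isfinite(curve)
        w_min = np.nanmin(curve)
        cands, flagged = _width_candidates(w_min * 0.95, curve, width_map.dz_grid)
        assert flagged
        assert len(cands) == 1


class TestInferZFromIntensity:
    def _trace(self, n=20):
        from mfi3d.flagellum3d import FlagellumTrace2D

        s = np.arange(n) * DEFAULT_ARC_PITCH_UM
        pts = np.column_stack([np.full(n, 16.0), np.full(n, 16.0)])
        return FlagellumTrace2D(pts, s, PITCH)

    def _frame_with_plane_intensities(self, values):
        planes = np.stack([np.full((32, 32), v) for v in values])
        return MultifocalFrame(planes, OFFSETS, PITCH)

    def test_symmetric_about_plane2(self):
        frame = self._frame_with_plane_intensities([1.0, 5.0, 1.0, 0.1])
        # symmetric around plane 2's offset in log space
        logs = np.array([1.0, 5.0, 1.0])
        z, ok = infer_z_from_intensity(self._trace(), frame)
        assert ok.all()
        np.testing.assert_allclose(z, OFFSETS[1], atol=0.3)

    def test_point_between_planes(self, flagellum_optics, psf):
        z_true = 4.4
        points = straight_filament_points(z=z_true)
        frame = render_filament(points, flagellum_optics, psf, noise=0.0)
        trace = extract_centerline_2d(frame.planes[1], PITCH)
        z, ok = infer_z_from_intensity(trace, frame)
        interior = ok & (trace.s > 5) & (trace.s < 35)
        assert np.median(z[interior]) == pytest.approx(z_true, abs=0.5)

    def test_monotone_profile_flagged(self):
        frame = self._frame_with_plane_intensities([1.0, 2.0, 4.0, 8.0])
        z, ok = infer_z_from_intensity(self._trace(), frame)
        assert not ok.any()


class TestSmoothArclength:
    def test_constant_unchanged(self):
        z = np.full(50, 3.0)
        np.testing.assert_allclose(smooth_arclength(z), 3.0)

    def test_outlier_suppressed(self):
        z = np.zeros(60)
        z[30] = 3.0
        out = smooth_arclength(z)
        assert np.abs(out).max() < 0.5

    def test_linear_ramp_preserved(self):
        z = np.linspace(0.0, 5.0, 100)
        out = smooth_arclength(z)
        interior = slice(8, -8)
        np.testing.assert_allclose(out[interior], z[interior], rtol=0.01, atol=0.02)


class TestEndToEnd:
    def test_beating_flagellum_reconstruction(
        self, flagellum_optics, psf, width_map, beat_spec
    ):
        """Short end-to-end chain: render a beating flagellum, reconstruct,
        and compare z to ground truth distal to the head region."""
        n_frames = 8
        centerlines = simulate_flagellar_beat(
            beat_spec, n_frames, origin=(6.0, 18.0, 4.4)
        )
        frames = []
        for t in range(n_frames):
            frames.append(
                render_filament(centerlines[t], flagellum_optics, psf, seed=600 + t)
            )
        trace3d = reconstruct_video(
            frames,
            width_map,
            head_hint=(centerlines[0, 0, 0] / PITCH, centerlines[0, 0, 1] / PITCH),
        )
        s_truth = np.arange(centerlines.shape[1]) * beat_spec.arc_pitch
        errors = []
        lengths = []
        for t in range(n_frames):
            z = trace3d.positions[t, :, 2]
            z_true = np.interp(trace3d.s, s_truth, centerlines[t, :, 2])
            distal = (trace3d.s > 10) & np.isfinite(z)
            errors.append(z[distal] - z_true[distal])
            xy = trace3d.positions[t, :, :2]
            fin = np.all(np.isfinite(xy), axis=1)
            lengths.append(
                np.linalg.norm(np.diff(xy[fin], axis=0), axis=1).sum()
            )
        rmse = np.sqrt(np.mean(np.concatenate(errors) ** 2))
        assert rmse <= 0.6
        # inextensible flagellum: traced arc length stable over time
        lengths = np.asarray(lengths)
        assert lengths.std() / lengths.mean() < 0.02

    def test_width_and_intensity_z_agree(self, flagellum_optics, psf, width_map):
        points = straight_filament_points(length=45.0, z=4.4, origin=(5.0, 30.0))
        frame = render_filament(points, flagellum_optics, psf, seed=31)
        trace = extract_centerline_2d(frame.planes[1], PITCH)
        measure_width_profile(frame, trace)
        z_w, ok_w = infer_flagellar_z(trace, width_map, OFFSETS)
        z_i, ok_i = infer_z_from_intensity(trace, frame)
        both = ok_w & ok_i & (trace.s > 10) & (trace.s < 40)
        assert both.sum() > 30
        assert abs(np.nanmedian(z_w[both]) - np.nanmedian(z_i[both])) < 1.0
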