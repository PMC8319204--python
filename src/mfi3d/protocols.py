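"""End-to-end synthetic experiment protocols.

Bundles the multi-module pipelines used for validation into reusable,
seedable functions: the bead calibration-validation experiment (render
calibration beads, build the radius-vs-z calibration, infer z for independent
validation beads, regress inferred against true z), the Brownian
precision-recovery experiment, and the full flagellum reconstruction chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mfi3d.bead3d import (
    BeadTrack,
    build_radius_calibration,
    infer_bead_z,
    measure_bead_radius,
)
from mfi3d.brownian_stats import estimate_precision, fit_displacement_distribution
from mfi3d.optics_forward import (
    Bead,
    BeatWaveformSpec,
    DiffusionModel,
    Filament,
    GaussianPSFModel,
    OpticsConfig,
    SceneSpec,
    render_multifocal_frame,
    simulate_brownian_track,
    simulate_flagellar_beat,
)

REFERENCE_PLANE_OFFSETS = np.array([0.0, 2.9, 5.9, 8.8])


def reference_optics(fov_px=(40, 40)) -> OpticsConfig:
    return OpticsConfig(fov_px=fov_px, plane_offsets=REFERENCE_PLANE_OFFSETS.copy())


def reference_psf() -> GaussianPSFModel:
    return GaussianPSFModel(w0=1.0, wavelength=0.53)


def _bead_sweep(optics, psf, z_values, seed, center_px=(20.0, 20.0)):
    pitch = optics.pixel_pitch_sample
    cx, cy = center_px
    fits = []
    for j, z in enumerate(z_values):
        scene = SceneSpec(
            objects=[Bead(center=(cx * pitch, cy * pitch, z))],
            seed=seed * 10_000 + j,
        )
        frame = render_multifocal_frame(scene, optics, psf)
        fits.append(
            [measure_bead_radius(frame.planes[k], (cx, cy)) for k in range(4)]
        )
    return fits


@dataclass
class CalibrationValidationResult:
    z_grid: np.ndarray
    slopes: np.ndarray  # per validation bead
    residual_sd: np.ndarray  # per validation bead, µm
    predicted_sigma_mean: float  # µm, mean combined precision over depth
    predicted_sigma_rms: float  # µm, RMS of the per-detection predictions
    n_excluded: int

    @property
    def mean_slope(self) -> float:
        return float(self.slopes.mean())


def calibration_validation_experiment(
    seed: int = 1,
    z_step: float = 0.1,
    z_half_range: float = 10.5,
    n_calibration: int = 7,
    n_validation: int = 5,
) -> CalibrationValidationResult:
    """Render calibration and validation bead z-sweeps; regress inferred z.

    Calibration beads build the radius-vs-z curves; each validation bead is
    rendered independently at every z step (2% read noise), localized through
    the full per-plane circle-fit / two-candidate / minimum-spread pipeline,
    and a line is fitted to inferred-vs-true z per bead.
    """
    optics = reference_optics()
    psf = reference_psf()
    z_grid = np.arange(-z_half_range, z_half_range + z_step / 2, z_step)
    rng = np.random.default_rng(seed)
    cal_seeds = rng.integers(0, 2**31 - 1, n_calibration)
    val_seeds = rng.integers(0, 2**31 - 1, n_validation)

    profiles = np.empty((n_calibration, 4, len(z_grid)))
    for i, s in enumerate(cal_seeds):
        fits = _bead_sweep(optics, psf, z_grid, int(s))
        profiles[i] = np.array([[f.radius for f in row] for row in fits]).T
    calibration = build_radius_calibration(
        profiles, z_grid, pixel_pitch=optics.pixel_pitch_sample
    )
    from mfi3d.bead3d import predict_z_precision

    _, predicted_mean = predict_z_precision(calibration)

    slopes = np.empty(n_validation)
    residual_sd = np.empty(n_validation)
    sigma_pred_all = []
    n_excluded = 0
    for i, s in enumerate(val_seeds):
        fits = _bead_sweep(optics, psf, z_grid, int(s))
        z_true, z_inf = [], []
        for j, z in enumerate(z_grid):
            inference = infer_bead_z(fits[j], calibration)
            if inference.excluded:
                n_excluded += 1
                continue
            z_true.append(z)
            z_inf.append(inference.z)
            if np.isfinite(inference.sigma_z):
                sigma_pred_all.append(inference.sigma_z)
        z_true = np.asarray(z_true)
        z_inf = np.asarray(z_inf)
        slope, intercept = np.polyfit(z_true, z_inf, 1)
        slopes[i] = slope
        residual_sd[i] = float(np.std(z_inf - (slope * z_true + intercept)))
    sigma_rms = float(np.sqrt(np.mean(np.square(sigma_pred_all))))
    return CalibrationValidationResult(
        z_grid, slopes, residual_sd, predicted_mean, sigma_rms, n_excluded
    )


def brownian_recovery_experiment(
    injected_sigma_um: float,
    seed: int = 1,
    n_beads: int = 81,
    n_frames: int = 1650,
    axis: str = "z",
) -> float:
    """Simulate diffusing beads with injected localization noise and recover
    the precision through the variance-sum inversion.

    The injected value is the displacement-error scale of the variance-sum
    identity; per-position noise is ``injected / sqrt(2)``. Returns the
    recovered sigma_P (µm).
    """
    model = DiffusionModel(
        temperature=295.0,
        viscosity=0.95e-3,
        particle_radius=250e-9,
        frame_period=2e-3,
    )
    rng = np.random.default_rng(seed)
    tracks = []
    for i in range(n_beads):
        pos = simulate_brownian_track(model, n_frames, (0.0, 0.0, 0.0), rng)
        noisy = pos + rng.normal(0.0, injected_sigma_um / math.sqrt(2.0), pos.shape)
        tracks.append(BeadTrack(i, np.arange(len(pos)), noisy))
    dist = fit_displacement_distribution(tracks, axis, model.frame_period)
    return estimate_precision(dist, model).sigma_p


@dataclass
class FlagellumPipelineResult:
    peak_frequency: float  # Hz from the Welch spectrum of kappa(t)
    z_rmse_distal: float  # µm, s > 10 µm
    harmonics: tuple[float, float, float]  # C0, C1, C2 of the reconstruction
    n_frames: int


def flagellum_pipeline_experiment(
    seed: int = 1,
    n_frames: int = 250,
    beat: BeatWaveformSpec | None = None,
) -> FlagellumPipelineResult:
    """Full chain: simulate a beating flagellum, render four planes, build a
    width calibration from an immotile sweep, reconstruct the 3D waveform and
    measure its frequency content and distal z error."""
    from mfi3d.beat_metrics import power_spectrum, signed_curvature
    from mfi3d.flagellum3d import (
        build_width_calibration,
        extract_centerline_2d,
        measure_width_profile,
        reconstruct_video,
        select_sharpest_plane,
        widths_on_grid,
    )
    from mfi3d.optics_forward import DEFAULT_ARC_PITCH_UM

    if beat is None:
        beat = BeatWaveformSpec(
            c0=0.02, c1=0.05, c2=0.006, f0=25.0, out_of_plane_amplitude=1.0
        )
    optics = reference_optics(fov_px=(160, 170))
    psf = reference_psf()
    pitch = optics.pixel_pitch_sample
    rng = np.random.default_rng(seed)

    # width calibration from an immotile cell swept through z
    s_grid = np.arange(0.0, beat.length, DEFAULT_ARC_PITCH_UM)
    immotile = BeatWaveformSpec(
        c0=beat.c0, c1=beat.c1, c2=beat.c2, f0=beat.f0, length=beat.length
    )
    base = simulate_flagellar_beat(immotile, 1, origin=(6.0, 18.0, 0.0))[0]
    piezo = np.arange(-2.0, 11.01, 0.2)
    cell = np.full((len(piezo), 4, len(s_grid)), np.nan)
    for j, zp in enumerate(piezo):
        pts = base.copy()
        pts[:, 2] = zp
        scene = SceneSpec(
            objects=[Filament(points=pts)], seed=int(rng.integers(0, 2**31 - 1))
        )
        frame = render_multifocal_frame(scene, optics, psf)
        trace = extract_centerline_2d(
            frame.planes[select_sharpest_plane(frame)],
            pitch,
            head_hint=(base[0, 0] / pitch, base[0, 1] / pitch),
        )
        measure_width_profile(frame, trace)
        cell[j] = widths_on_grid(trace, s_grid)
    width_map = build_width_calibration([cell], piezo, optics.plane_offsets, s_grid)

    # beating flagellum video
    centerlines = simulate_flagellar_beat(beat, n_frames, origin=(6.0, 18.0, 4.4))
    frames = []
    for t in range(n_frames):
        scene = SceneSpec(
            objects=[Filament(points=centerlines[t])],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        frames.append(
            render_multifocal_frame(scene, optics, psf, t / beat.frame_rate)
        )
    trace3d = reconstruct_video(
        frames,
        width_map,
        frame_rate=beat.frame_rate,
        head_hint=(centerlines[0, 0, 0] / pitch, centerlines[0, 0, 1] / pitch),
    )

    # distal z error vs ground truth
    s_truth = np.arange(centerlines.shape[1]) * beat.arc_pitch
    errors = []
    for t in range(n_frames):
        z = trace3d.positions[t, :, 2]
        z_true = np.interp(trace3d.s, s_truth, centerlines[t, :, 2])
        distal = (trace3d.s > 10.0) & np.isfinite(z)
        errors.append(z[distal] - z_true[distal])
    z_rmse = float(np.sqrt(np.mean(np.concatenate(errors) ** 2)))

    # beat frequency and harmonics from the reconstructed curvature field
    from mfi3d.beat_metrics import harmonic_components

    field = signed_curvature(trace3d.positions, trace3d.s)
    i_arc = int(np.argmin(np.abs(trace3d.s - 33.0)))
    series = field.kappa[:, i_arc]
    series = np.where(np.isfinite(series), series, np.nanmedian(series))
    spectrum = power_spectrum(series, beat.frame_rate)
    harmonics = harmonic_components(series, beat.frame_rate, spectrum.peak_frequency)
    return FlagellumPipelineResult(
        spectrum.peak_frequency, z_rmse, harmonics, n_frames
    )
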