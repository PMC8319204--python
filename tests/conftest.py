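"""Shared fixtures: a reference optical configuration and rendered scenes.

Session-scoped fixtures cache expensive renders (bead z-sweeps, flagellum
calibration stacks) so that multiple tests can reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from mfi3d.bead3d import build_radius_calibration, measure_bead_radius
from mfi3d.optics_forward import (
    Bead,
    BeatWaveformSpec,
    Filament,
    GaussianPSFModel,
    OpticsConfig,
    SceneSpec,
    render_multifocal_frame,
    simulate_flagellar_beat,
)

PLANE_OFFSETS = np.array([0.0, 2.9, 5.9, 8.8])
Z_GRID = np.arange(-10.5, 10.55, 0.1)


@pytest.fixture(scope="session")
def optics() -> OpticsConfig:
    return OpticsConfig(fov_px=(40, 40), plane_offsets=PLANE_OFFSETS.copy())


@pytest.fixture(scope="session")
def psf() -> GaussianPSFModel:
    return GaussianPSFModel(w0=1.0, wavelength=0.53)


def render_bead_sweep(optics, psf, z_values, seed, center_px=(20.0, 20.0)):
    """Radius profile of one bead across a z sweep; returns (4, nz) px."""
    pitch = optics.pixel_pitch_sample
    cx, cy = center_px
    prof = np.empty((4, len(z_values)))
    fits = []
    for j, z in enumerate(z_values):
        scene = SceneSpec(
            objects=[Bead(center=(cx * pitch, cy * pitch, z))],
            seed=seed * 10_000 + j,
        )
        frame = render_multifocal_frame(scene, optics, psf)
        row = [measure_bead_radius(frame.planes[k], (cx, cy)) for k in range(4)]
        fits.append(row)
        prof[:, j] = [f.radius for f in row]
    return prof, fits


@pytest.fixture(scope="session")
def coarse_z_grid() -> np.ndarray:
    # 0.3 µm steps keep the unit-test renders fast; the acceptance suite
    # runs the full 0.1 µm protocol
    return np.arange(-10.5, 10.6, 0.3)


@pytest.fixture(scope="session")
def bead_calibration(optics, psf, coarse_z_grid):
    profiles = np.stack(
        [render_bead_sweep(optics, psf, coarse_z_grid, seed)[0] for seed in range(3)]
    )
    return build_radius_calibration(
        profiles, coarse_z_grid, pixel_pitch=optics.pixel_pitch_sample
    )


@pytest.fixture(scope="session")
def flagellum_optics() -> OpticsConfig:
    return OpticsConfig(fov_px=(160, 170), plane_offsets=PLANE_OFFSETS.copy())


@pytest.fixture(scope="session")
def beat_spec() -> BeatWaveformSpec:
    return BeatWaveformSpec(
        c0=0.02, c1=0.05, c2=0.006, f0=25.0, out_of_plane_amplitude=1.0
    )


def render_flagellum_frame(flagellum_optics, psf, points, seed):
    scene = SceneSpec(objects=[Filament(points=points)], seed=seed)
    return render_multifocal_frame(scene, flagellum_optics, psf)


@pytest.fixture(scope="session")
def width_map(flagellum_optics, psf):
    """Width calibration from one immotile synthetic flagellum z-sweep."""
    from mfi3d.flagellum3d import (
        build_width_calibration,
        extract_centerline_2d,
        measure_width_profile,
        select_sharpest_plane,
        widths_on_grid,
    )
    from mfi3d.optics_forward import DEFAULT_ARC_PITCH_UM

    pitch = flagellum_optics.pixel_pitch_sample
    s_grid = np.arange(0.0, 50.0, DEFAULT_ARC_PITCH_UM)
    cal_spec = BeatWaveformSpec(c0=0.02, c1=0.05, c2=0.006, f0=25.0)
    base = simulate_flagellar_beat(cal_spec, 1, origin=(6.0, 18.0, 0.0))[0]
    piezo = np.arange(-2.0, 11.01, 0.2)
    cell = np.full((len(piezo), 4, len(s_grid)), np.nan)
    for j, zp in enumerate(piezo):
        pts = base.copy()
        pts[:, 2] = zp
        frame = render_flagellum_frame(flagellum_optics, psf, pts, 4_000 + j)
        trace = extract_centerline_2d(
            frame.planes[select_sharpest_plane(frame)],
            pitch,
            head_hint=(base[0, 0] / pitch, base[0, 1] / pitch),
        )
        measure_width_profile(frame, trace)
        cell[j] = widths_on_grid(trace, s_grid)
    return build_width_calibration(
        [cell], piezo, flagellum_optics.plane_offsets, s_grid
    )
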