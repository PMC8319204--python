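"""Optical forward model and synthetic multifocal data generation.

Implements a Gaussian-beam defocus model: a point at axial distance ``z`` from
a focal plane images as a Gaussian of width ``w(z) = w0 * sqrt(1 + (z/z_R)**2)``
with transverse profile ``exp(-r**2 / w(z)**2)``. Scenes of beads, filaments
and calibration grids are rendered into four focal-plane images at once, and
simple motion models (Brownian diffusion, curvature-wave flagellar beating)
provide ground-truth trajectories for the downstream reconstruction modules.

Coordinate conventions: x right / y down in pixel space, pixel centers at
integer coordinates (0-based); z in µm, increasing away from the objective,
with z = 0 at the focus of plane 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from mfi3d.frame import N_PLANES, MultifocalFrame

BOLTZMANN_J_PER_K = 1.380649e-23

#: default arc-length sampling pitch for synthetic flagella (µm); equals the
#: sample-space pixel pitch of the reference configuration (11/32 µm/px).
DEFAULT_ARC_PITCH_UM = 11.0 / 32.0

#: kernels are truncated at 4 * w(z); in sigma units (sigma = w / sqrt(2))
#: this is 4 * sqrt(2) sigmas, i.e. < 1e-3 relative mass loss.
PSF_TRUNCATE_SIGMAS = 4.0 * math.sqrt(2.0)


class InvalidConfigError(ValueError):
    """Raised for non-physical optics parameters."""


class SingularGeometryError(ValueError):
    """Raised when a relay configuration images to infinity."""


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------


@dataclass
class OpticsConfig:
    """Imaging-system parameters.

    ``plane_offsets`` are the sample-space focal positions of the four planes
    (µm, relative to plane 1) and must be strictly monotonic.
    """

    numerical_aperture: float = 0.5
    refractive_index: float = 1.0
    wavelength: float = 0.53
    pixel_size_physical: float = 11.0
    magnification: float = 32.0
    plane_offsets: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 2.9, 5.9, 8.8])
    )
    fov_px: tuple[int, int] = (128, 128)
    lens_focal_lengths: tuple[float, ...] = (math.inf, 1000.0, 750.0, 500.0)

    def __post_init__(self) -> None:
        self.plane_offsets = np.asarray(self.plane_offsets, dtype=float)
        for name in (
            "numerical_aperture",
            "refractive_index",
            "wavelength",
            "pixel_size_physical",
            "magnification",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.plane_offsets.shape != (N_PLANES,):
            raise InvalidConfigError("plane_offsets must have length 4")
        diffs = np.diff(self.plane_offsets)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise InvalidConfigError("plane_offsets must be strictly monotonic")

    @property
    def pixel_pitch_sample(self) -> float:
        """Sample-plane pixel pitch in µm/px."""
        return self.pixel_size_physical / self.magnification


def abbe_limit(config: OpticsConfig) -> float:
    """Lateral resolution bound r_z = (n/NA) * [lambda/NA + e_pixel/M] in µm."""
    return (config.refractive_index / config.numerical_aperture) * (
        config.wavelength / config.numerical_aperture
        + config.pixel_size_physical / config.magnification
    )


@dataclass
class GaussianPSFModel:
    """Gaussian-beam defocus model: waist ``w0`` (µm) and wavelength (µm)."""

    w0: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.w0 <= 0 or self.wavelength <= 0:
            raise InvalidConfigError("w0 and wavelength must be positive")

    @property
    def rayleigh_range(self) -> float:
        """z_R = pi * w0**2 / lambda (µm)."""
        return math.pi * self.w0**2 / self.wavelength

    @classmethod
    def from_optics(
        cls, config: OpticsConfig, w0: float | None = None
    ) -> "GaussianPSFModel":
        """Build from an optics configuration.

        ``w0`` defaults to the Abbe limit of the configuration; it is kept a
        free parameter because the resolution actually realized depends on the
        condenser geometry and is best measured.
        """
        return cls(w0=abbe_limit(config) if w0 is None else w0,
                   wavelength=config.wavelength)


def psf_width(z_offset: float | np.ndarray, model: GaussianPSFModel):
    """Beam width w(z) = w0 * sqrt(1 + (z/z_R)**2); even in z. Units µm."""
    z = np.asarray(z_offset, dtype=float)
    w = model.w0 * np.sqrt(1.0 + (z / model.rayleigh_range) ** 2)
    return float(w) if np.isscalar(z_offset) else w


def _psf_sigma_px(z_offset: float, model: GaussianPSFModel, pitch: float) -> float:
    # intensity profile exp(-r^2/w^2) is a Gaussian with sigma = w/sqrt(2)
    return psf_width(z_offset, model) / math.sqrt(2.0) / pitch


# --------------------------------------------------------------------------
# scene description
# --------------------------------------------------------------------------


@dataclass
class Bead:
    """Spherical scatterer: rendered as a disc of its physical radius."""

    center: tuple[float, float, float]  # x, y, z in µm
    radius: float = 0.25
    brightness: float = 100.0


@dataclass
class Filament:
    """Thin curvilinear scatterer given as a 3D polyline (µm)."""

    points: np.ndarray  # (N, 3) µm
    thickness: float = 0.25
    brightness: float = 100.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("filament points must have shape (N, 3)")


@dataclass
class Grid:
    """Square calibration grid of bright lines at a single depth."""

    pitch: float = 10.0  # µm
    line_width: float = 1.0  # µm
    z: float = 0.0
    brightness: float = 100.0


@dataclass
class SceneSpec:
    """Objects plus background and noise model for one rendered frame."""

    objects: list
    background: float = 0.0
    read_noise_frac: float = 0.02  # sd as fraction of the noise-free peak
    read_noise_sd: float | None = None  # absolute counts; overrides the fraction
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for obj in self.objects:
            if getattr(obj, "brightness", 0.0) < 0:
                raise ValueError("brightness must be >= 0")
            coords = None
            if isinstance(obj, Bead):
                coords = np.asarray(obj.center, dtype=float)
            elif isinstance(obj, Filament):
                coords = obj.points
            if coords is not None and not np.all(np.isfinite(coords)):
                raise ValueError("object coordinates must be finite")


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def _add_patch(image: np.ndarray, patch: np.ndarray, top: int, left: int) -> None:
    """Add ``patch`` into ``image`` at (top, left), clipping at the borders."""
    h, w = image.shape
    ph, pw = patch.shape
    y0, y1 = max(top, 0), min(top + ph, h)
    x0, x1 = max(left, 0), min(left + pw, w)
    if y0 >= y1 or x0 >= x1:
        return
    image[y0:y1, x0:x1] += patch[y0 - top : y1 - top, x0 - left : x1 - left]


def _render_bead(
    image: np.ndarray,
    bead: Bead,
    sigma_px: float,
    pitch: float,
    supersample: int = 4,
) -> None:
    x_px = bead.center[0] / pitch
    y_px = bead.center[1] / pitch
    r_px = bead.radius / pitch
    half = int(math.ceil(r_px + PSF_TRUNCATE_SIGMAS * max(sigma_px, 0.5) + 2))
    cx, cy = int(round(x_px)), int(round(y_px))
    n = 2 * half + 1
    ss = supersample
    # supersampled coordinates of sub-pixel centers, in native px units
    ax = (np.arange(n * ss) - (ss - 1) / 2.0) / ss
    gx = cx - half + ax
    gy = cy - half + ax
    dist2 = (gx[None, :] - x_px) ** 2 + (gy[:, None] - y_px) ** 2
    patch = np.where(dist2 <= r_px**2, bead.brightness, 0.0)
    if sigma_px > 0:
        patch = gaussian_filter(
            patch, sigma_px * ss, truncate=PSF_TRUNCATE_SIGMAS, mode="constant"
        )
    # block-average back to the native grid (area sampling)
    patch = patch.reshape(n, ss, n, ss).mean(axis=(1, 3))
    _add_patch(image, patch, cy - half, cx - half)


def _gaussian_patch(x_px: float, y_px: float, sigma_px: float) -> tuple:
    """Unit-sum 2D Gaussian sampled on the native grid around (x_px, y_px)."""
    half = int(math.ceil(PSF_TRUNCATE_SIGMAS * sigma_px + 1))
    cx, cy = int(round(x_px)), int(round(y_px))
    ax = np.arange(2 * half + 1)
    gx = cx - half + ax - x_px
    gy = cy - half + ax - y_px
    patch = np.exp(
        -(gx[None, :] ** 2 + gy[:, None] ** 2) / (2.0 * sigma_px**2)
    )
    s = patch.sum()
    if s > 0:
        patch /= s
    return patch, cy - half, cx - half


def _render_filament(
    image: np.ndarray,
    fil: Filament,
    plane_z: float,
    psf: GaussianPSFModel,
    pitch: float,
) -> None:
    # resample the polyline at ~half-pixel arc spacing and deposit one
    # flux-conserving Gaussian per sample (depth-dependent width)
    pts = fil.points
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total <= 0:
        return
    ds = pitch / 2.0
    s_samples = np.arange(0.0, total, ds)
    xs = np.interp(s_samples, arclen, pts[:, 0])
    ys = np.interp(s_samples, arclen, pts[:, 1])
    zs = np.interp(s_samples, arclen, pts[:, 2])
    # flux per sample: brightness * thickness * ds, in counts*px^2
    flux = fil.brightness * fil.thickness * ds / pitch**2
    for x, y, z in zip(xs, ys, zs):
        sigma_px = _psf_sigma_px(z - plane_z, psf, pitch)
        # fold the physical thickness into the Gaussian footprint
        sigma_eff = math.sqrt(sigma_px**2 + (fil.thickness / 4.0 / pitch) ** 2)
        patch, top, left = _gaussian_patch(x / pitch, y / pitch, sigma_eff)
        _add_patch(image, patch * flux, top, left)


def _render_grid(
    image: np.ndarray,
    grid: Grid,
    sigma_px: float,
    pitch: float,
    supersample: int = 2,
) -> None:
    h, w = image.shape
    ss = supersample
    ax_x = (np.arange(w * ss) - (ss - 1) / 2.0) / ss * pitch
    ax_y = (np.arange(h * ss) - (ss - 1) / 2.0) / ss * pitch
    on_x = np.mod(ax_x, grid.pitch) < grid.line_width
    on_y = np.mod(ax_y, grid.pitch) < grid.line_width
    mask = np.logical_or(on_y[:, None], on_x[None, :])
    patch = mask.astype(float) * grid.brightness
    if sigma_px > 0:
        patch = gaussian_filter(
            patch, sigma_px * ss, truncate=PSF_TRUNCATE_SIGMAS, mode="nearest"
        )
    image += patch.reshape(h, ss, w, ss).mean(axis=(1, 3))


def render_multifocal_frame(
    scene: SceneSpec,
    config: OpticsConfig,
    psf: GaussianPSFModel,
    timestamp: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MultifocalFrame:
    """Render a scene into the four focal planes.

    Each object's in-focus footprint is convolved with the Gaussian PSF of
    width ``w(z_obj - plane_offset)`` per plane, so the integrated (noise-free)
    intensity of an isolated object is conserved across planes. Noise is
    applied last: optional Poisson shot noise, then additive Gaussian read
    noise, then clipping at zero counts.

    Passing ``rng`` continues an existing noise stream (for video rendering);
    otherwise a fresh generator seeded from ``scene.seed`` is used, which
    makes single-frame rendering bit-reproducible.
    """
    pitch = config.pixel_pitch_sample
    h, w = config.fov_px
    planes = np.zeros((N_PLANES, h, w), dtype=float)
    for k, offset in enumerate(config.plane_offsets):
        img = planes[k]
        for obj in scene.objects:
            if isinstance(obj, Bead):
                sigma_px = _psf_sigma_px(obj.center[2] - offset, psf, pitch)
                _render_bead(img, obj, sigma_px, pitch)
            elif isinstance(obj, Filament):
                _render_filament(img, obj, offset, psf, pitch)
            elif isinstance(obj, Grid):
                sigma_px = _psf_sigma_px(obj.z - offset, psf, pitch)
                _render_grid(img, obj, sigma_px, pitch)
            else:  # pragma: no cover - defensive
                raise TypeError(f"unknown scene object {type(obj)!r}")
    planes += scene.background

    if rng is None:
        rng = np.random.default_rng(scene.seed)
    if scene.poisson:
        planes = rng.poisson(np.clip(planes, 0, None)).astype(float)
    sd = scene.read_noise_sd
    if sd is None:
        sd = scene.read_noise_frac * max(planes.max() - scene.background, 0.0)
    if sd > 0:
        planes = planes + rng.normal(0.0, sd, size=planes.shape)
    planes = np.clip(planes, 0.0, None)
    return MultifocalFrame(planes, config.plane_offsets, pitch, timestamp)


# --------------------------------------------------------------------------
# motion models
# --------------------------------------------------------------------------


@dataclass
class DiffusionModel:
    """Stokes–Einstein diffusion of a sphere.

    D = k_B * T / (6 * pi * eta * R_p); per-axis step variance over one frame
    period is 2 * D * dt.
    """

    temperature: float = 295.0  # K
    viscosity: float = 0.95e-3  # kg m^-1 s^-1
    particle_radius: float = 250e-9  # m
    frame_period: float = 2e-3  # s
    diffusion_coefficient: float | None = None  # m^2 s^-1 override

    @property
    def d_m2_per_s(self) -> float:
        if self.diffusion_coefficient is not None:
            return self.diffusion_coefficient
        return BOLTZMANN_J_PER_K * self.temperature / (
            6.0 * math.pi * self.viscosity * self.particle_radius
        )

    @property
    def d_um2_per_s(self) -> float:
        return self.d_m2_per_s * 1e12

    @property
    def step_sigma_um(self) -> float:
        """Per-axis displacement sd over one frame period (µm)."""
        return math.sqrt(2.0 * self.d_um2_per_s * self.frame_period)


def simulate_brownian_track(
    model: DiffusionModel,
    n_steps: int,
    start: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate isotropic diffusion; returns (n_steps + 1, 3) positions in µm."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    steps = rng.normal(0.0, model.step_sigma_um, size=(n_steps, 3))
    track = np.empty((n_steps + 1, 3))
    track[0] = start
    track[1:] = np.asarray(start, dtype=float) + np.cumsum(steps, axis=0)
    return track


@dataclass
class BeatWaveformSpec:
    """Curvature-wave description of a beating flagellum.

    The planar curvature field is
    kappa(s, t) = C0 + C1*cos(2*pi*f0*t - 2*pi*s/wavelength_arc)
                     + C2*cos(4*pi*f0*t - 4*pi*s/wavelength_arc),
    integrated to a centerline of length L; an out-of-plane traveling
    z-displacement of the given amplitude is superposed.
    """

    c0: float = 0.0  # µm^-1
    c1: float = 0.05  # µm^-1
    c2: float = 0.0  # µm^-1
    f0: float = 25.0  # Hz
    wavelength_arc: float = 25.0  # µm
    length: float = 50.0  # µm
    out_of_plane_amplitude: float = 0.0  # µm
    frame_rate: float = 500.0  # Hz
    arc_pitch: float = DEFAULT_ARC_PITCH_UM  # µm

    def __post_init__(self) -> None:
        if self.length <= 0 or self.f0 <= 0:
            raise ValueError("length and f0 must be positive")
        if min(self.c1, self.c2) < 0:
            raise ValueError("curvature amplitudes must be >= 0")


def beat_curvature(spec: BeatWaveformSpec, s: np.ndarray, t: float) -> np.ndarray:
    """Evaluate the prescribed curvature field kappa(s, t)."""
    phase = 2.0 * math.pi * (spec.f0 * t - s / spec.wavelength_arc)
    return spec.c0 + spec.c1 * np.cos(phase) + spec.c2 * np.cos(2.0 * phase)


def simulate_flagellar_beat(
    spec: BeatWaveformSpec,
    n_frames: int,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Generate centerlines for ``n_frames`` timepoints.

    Returns an array of shape (n_frames, n_points, 3) in µm, sampled at the
    spec's fixed arc-length pitch; total 3D arc length equals ``spec.length``
    within 0.1% per frame (exactly, up to the last partial sample).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ds = spec.arc_pitch
    # integrate on a slightly longer planar domain so that after adding the
    # out-of-plane component the 3D curve still reaches full length
    margin = 1.0
    if spec.out_of_plane_amplitude > 0:
        slope = 2.0 * math.pi * spec.out_of_plane_amplitude / spec.wavelength_arc
        margin = math.sqrt(1.0 + slope**2) * 1.02
    n_int = int(math.ceil(spec.length * margin / ds)) + 2
    s_int = np.arange(n_int) * ds
    n_out = int(math.floor(spec.length / ds)) + 1
    s_out = np.arange(n_out) * ds

    frames = np.empty((n_frames, n_out, 3))
    origin = np.asarray(origin, dtype=float)
    for i in range(n_frames):
        t = i / spec.frame_rate
        kappa = beat_curvature(spec, s_int, t)
        # tangent angle by trapezoidal integration of curvature
        psi = np.concatenate(
            [[0.0], np.cumsum(0.5 * (kappa[1:] + kappa[:-1]) * ds)]
        )
        # step with unit tangents at midpoint angles: every planar segment
        # has length exactly ds
        mid = 0.5 * (psi[1:] + psi[:-1])
        x = np.concatenate([[0.0], np.cumsum(ds * np.cos(mid))])
        y = np.concatenate([[0.0], np.cumsum(ds * np.sin(mid))])
        z = spec.out_of_plane_amplitude * np.sin(
            2.0 * math.pi * (spec.f0 * t - s_int / spec.wavelength_arc)
        )
        pts = np.column_stack([x, y, z])
        # reparameterize by 3D arc length
        chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc3d = np.concatenate([[0.0], np.cumsum(chord)])
        if arc3d[-1] < spec.length:  # pragma: no cover - margin guard
            raise RuntimeError("integration domain too short")
        for j in range(3):
            frames[i, :, j] = np.interp(s_out, arc3d, pts[:, j])
        frames[i] += origin
    return frames


# --------------------------------------------------------------------------
# thin-lens plane-offset prediction
# --------------------------------------------------------------------------


def thin_lens_plane_offsets(
    config: OpticsConfig, lens_to_chip_mm: float
) -> np.ndarray:
    """Predict sample-space focal offsets of the four relay paths (µm).

    Each path holds a lens of focal length ``f`` (mm, ``inf`` = empty path) at
    ``lens_to_chip_mm`` before the camera chip. The converging bundle that
    would focus on the chip is refocused by the lens (1/f = 1/s + 1/s'),
    shifting the image plane by ``d**2 / (d + f)``; division by the axial
    magnification M**2 converts to sample space. Offsets are referenced to the
    lens-free path.
    """
    d = float(lens_to_chip_mm)
    if d <= 0:
        raise InvalidConfigError("lens_to_chip_mm must be positive")
    offsets = []
    for f in config.lens_focal_lengths:
        if math.isinf(f):
            offsets.append(0.0)
            continue
        if f == 0:
            raise InvalidConfigError("focal length must be nonzero")
        if abs(d + f) < 1e-9 * d:
            raise SingularGeometryError("image forms at infinity")
        shift_mm = d**2 / (d + f)
        offsets.append(shift_mm * 1e3 / config.magnification**2)
    return np.asarray(offsets)
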