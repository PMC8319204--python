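"""Bead detection, defocus calibration, and 3D localization.

The z-position of a bead is inferred from the radius of its defocused image:
an intensity-squared-weighted algebraic circle fit measures the radius in each
of the four planes, a per-plane calibration curve R_k(z) built from immobile
beads maps radius back to two candidate z-positions per plane (one above and
one below that plane's focus), and the cross-plane candidate combination with
the lowest standard deviation resolves the ambiguity. The reported precision
comes from error propagation through the inverse calibration curve,
sigma_z = |dz/dR| * sigma_R.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_laplace, maximum_filter

from mfi3d.frame import N_PLANES, MultifocalFrame
from mfi3d.plane_prep import _parabolic_refine


class SingularFitError(RuntimeError):
    pass


class AlignmentError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# video preprocessing
# --------------------------------------------------------------------------


def preprocess_video(
    frames: list[MultifocalFrame], subtract_static: bool = False
) -> tuple[np.ndarray, list[MultifocalFrame]]:
    """Maximum-intensity projection across planes, per timepoint.

    With ``subtract_static`` the per-pixel time-average is subtracted from
    every frame first (negatives clipped at zero), which removes nonmoving
    beads and background structure; requires at least two frames.
    """
    if not frames:
        raise ValueError("need at least one frame")
    if subtract_static and len(frames) < 2:
        raise ValueError("static subtraction requires >= 2 frames")
    cleaned = frames
    if subtract_static:
        mean = np.mean([f.planes for f in frames], axis=0)
        cleaned = []
        for f in frames:
            g = f.copy()
            g.planes = np.clip(f.planes - mean, 0.0, None)
            cleaned.append(g)
    projection = np.stack([f.planes.max(axis=0) for f in cleaned])
    return projection, cleaned


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------


def detect_beads(
    image: np.ndarray, diameter_px: float = 10.0, threshold: float = 50.0
) -> np.ndarray:
    """Laplacian-of-Gaussian blob detection with subpixel refinement.

    Returns an (N, 2) array of (x, y) centers. The LoG scale is
    ``diameter / (2 * sqrt(2))``; response maxima above ``threshold`` are
    kept with non-maximum suppression within one diameter, and centers are
    refined by a per-axis 3-point quadratic fit to the response.
    """
    if diameter_px < 3:
        raise ValueError("diameter_px must be >= 3")
    image = np.asarray(image, dtype=float)
    sigma = diameter_px / (2.0 * math.sqrt(2.0))
    # scale-normalized negative LoG: positive at bright blobs
    response = -(sigma**2) * gaussian_laplace(image, sigma)
    size = max(int(round(diameter_px)) | 1, 3)
    local_max = (response == maximum_filter(response, size=size)) & (
        response > threshold
    )
    ys, xs = np.nonzero(local_max)
    centers = []
    for y, x in zip(ys, xs):
        cx, cy = float(x), float(y)
        if 0 < x < image.shape[1] - 1:
            cx = _parabolic_refine(
                np.array([x - 1.0, x, x + 1.0]), -response[y, x - 1 : x + 2], 1
            )
        if 0 < y < image.shape[0] - 1:
            cy = _parabolic_refine(
                np.array([y - 1.0, y, y + 1.0]), -response[y - 1 : y + 2, x], 1
            )
        centers.append((cx, cy))
    return np.asarray(centers).reshape(-1, 2)


# --------------------------------------------------------------------------
# weighted algebraic circle fit
# --------------------------------------------------------------------------


@dataclass
class CircleFitPatch:
    """Pixels within a radius of a seed center, with their intensities."""

    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x.size < 6:
            raise ValueError("patch needs >= 6 pixels")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    @classmethod
    def from_image(
        cls, image: np.ndarray, center: tuple[float, float], radius_px: float = 10.0
    ) -> "CircleFitPatch":
        cx, cy = center
        x0 = max(int(math.floor(cx - radius_px)), 0)
        x1 = min(int(math.ceil(cx + radius_px)) + 1, image.shape[1])
        y0 = max(int(math.floor(cy - radius_px)), 0)
        y1 = min(int(math.ceil(cy + radius_px)) + 1, image.shape[0])
        ys, xs = np.mgrid[y0:y1, x0:x1]
        mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_px**2
        return cls(xs[mask], ys[mask], np.clip(image[y0:y1, x0:x1][mask], 0, None))


@dataclass
class CircleFitResult:
    """Solution of the linearized circle fit.

    ``r2`` is the radial-profile goodness used for quality gating: the
    coefficient of determination of the best radially symmetric intensity
    model about the fitted center. ``r2_linear`` is the weighted coefficient
    of determination of the linearized circle system itself (structurally
    bounded near 0.5 for filled radially symmetric images, hence unsuitable
    as an absolute-threshold gate).
    """

    center: tuple[float, float]
    b: float
    radius: float
    r2: float
    valid: bool = True
    r2_linear: float = float("nan")


def _radial_profile_r2(
    patch: CircleFitPatch, center: tuple[float, float], bin_px: float = 1.0
) -> float:
    """Goodness of the radially symmetric intensity model about ``center``."""
    rho = np.hypot(patch.x - center[0], patch.y - center[1])
    idx = (rho / bin_px).astype(int)
    intens = patch.intensity
    pred = np.empty_like(intens)
    for b in np.unique(idx):
        sel = idx == b
        pred[sel] = intens[sel].mean()
    ss_res = float(np.sum((intens - pred) ** 2))
    ss_tot = float(np.sum((intens - intens.mean()) ** 2))
    if ss_tot <= 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_circle_weighted(patch: CircleFitPatch) -> CircleFitResult:
    """Intensity-squared-weighted algebraic circle fit.

    Solves the overdetermined system ``2*x*xc + 2*y*yc + b = x**2 + y**2``
    by least squares with each row scaled by the squared pixel intensity,
    then recovers ``R = sqrt(xc**2 + yc**2 + b)``. A negative radius
    argument yields ``valid=False`` (excluded downstream).
    """
    w = patch.intensity**2
    if w.sum() <= 0:
        raise SingularFitError("all-zero weights")
    # shift to the weighted centroid for conditioning; residuals of the
    # linear system are shift-invariant, so r2 is computed in shifted
    # coordinates against the weighted mean
    x0 = np.average(patch.x, weights=w)
    y0 = np.average(patch.y, weights=w)
    u = patch.x - x0
    v = patch.y - y0
    a_mat = np.column_stack([2.0 * u, 2.0 * v, np.ones_like(u)]) * w[:, None]
    b_vec = (u**2 + v**2) * w
    try:
        sol, _, rank, _ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise SingularFitError(str(exc)) from exc
    if rank < 3:
        raise SingularFitError("degenerate (collinear) pixel configuration")
    uc, vc, b_shift = sol
    xc, yc = uc + x0, vc + y0
    r_sq = uc**2 + vc**2 + b_shift
    valid = r_sq >= 0
    radius = math.sqrt(r_sq) if valid else float("nan")
    res = a_mat @ sol - b_vec
    ss_res = float(res @ res)
    b_mean = np.average(u**2 + v**2, weights=w)
    ss_tot = float(np.sum((b_vec - b_mean * w) ** 2))
    r2_linear = (
        1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    )
    r2 = _radial_profile_r2(patch, (float(xc), float(yc)))
    b_abs = radius**2 - xc**2 - yc**2 if valid else float("nan")
    return CircleFitResult(
        (float(xc), float(yc)), float(b_abs), radius, r2, valid, r2_linear
    )


def measure_bead_radius(
    image: np.ndarray, center: tuple[float, float], radius_px: float = 10.0
) -> CircleFitResult:
    """Convenience: extract the patch around ``center`` and fit it."""
    return fit_circle_weighted(CircleFitPatch.from_image(image, center, radius_px))


# --------------------------------------------------------------------------
# radius-vs-z calibration
# --------------------------------------------------------------------------


@dataclass
class RadiusCalibration:
    """Per-plane radius-vs-z curves with spread and propagated z-precision.

    All curves share one uniform z grid (µm); radii are in px. ``sigma_z``
    is ``sigma_r / |dR/dz|`` evaluated on the smoothed curve and is infinite
    where the curve is flat (at each plane's focus).
    """

    z_grid: np.ndarray
    radius: np.ndarray  # (n_planes, nz)
    sigma_r: np.ndarray  # (n_planes, nz)
    sigma_z: np.ndarray  # (n_planes, nz)
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        steps = np.diff(self.z_grid)
        if not np.allclose(steps, steps[0]):
            raise ValueError("z grid must be uniform")

    @property
    def n_planes(self) -> int:
        return self.radius.shape[0]

    def radius_at(self, plane: int, z) -> np.ndarray:
        return np.interp(z, self.z_grid, self.radius[plane])

    def sigma_z_at(self, plane: int, z) -> np.ndarray:
        finite = np.where(np.isfinite(self.sigma_z[plane]), self.sigma_z[plane], np.nan)
        out = np.interp(z, self.z_grid, finite)
        return np.where(np.isnan(out), np.inf, out)

    def to_json(self, path) -> None:
        payload = {
            "z_grid": self.z_grid.tolist(),
            "radius": self.radius.tolist(),
            "sigma_r": self.sigma_r.tolist(),
            "sigma_z": np.where(
                np.isfinite(self.sigma_z), self.sigma_z, -1.0
            ).tolist(),
            "pixel_pitch": self.pixel_pitch,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RadiusCalibration":
        with open(path) as fh:
            payload = json.load(fh)
        sigma_z = np.asarray(payload["sigma_z"], dtype=float)
        sigma_z[sigma_z < 0] = np.inf
        return cls(
            np.asarray(payload["z_grid"], dtype=float),
            np.asarray(payload["radius"], dtype=float),
            np.asarray(payload["sigma_r"], dtype=float),
            sigma_z,
            payload.get("pixel_pitch", 1.0),
        )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return y.copy()
    half = window // 2
    out = np.empty_like(y, dtype=float)
    for i in range(len(y)):
        lo = max(i - half, 0)
        hi = min(i + half + 1, len(y))
        out[i] = np.nanmean(y[lo:hi])
    return out


def align_profiles(
    profiles: np.ndarray, z_grid: np.ndarray, max_lag_um: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Align per-bead radius profiles along z by least-mean-square matching.

    ``profiles`` has shape (n_beads, n_planes, nz). Bead 0 is the reference;
    every other bead is shifted (grid search over lags up to ``max_lag_um``,
    parabolic sub-step refinement) to minimize the mean squared difference
    across all planes. Returns (aligned profiles, per-bead z offsets in µm);
    shifted-out samples are NaN.
    """
    profiles = np.asarray(profiles, dtype=float)
    n_beads, n_planes, nz = profiles.shape
    dz = float(z_grid[1] - z_grid[0])
    max_lag = int(round(max_lag_um / dz))
    ref = profiles[0]
    aligned = np.full_like(profiles, np.nan)
    aligned[0] = ref
    offsets = np.zeros(n_beads)
    for i in range(1, n_beads):
        lags = np.arange(-max_lag, max_lag + 1)
        costs = np.full(len(lags), np.nan)
        for j, lag in enumerate(lags):
            lo, hi = max(lag, 0), min(nz + lag, nz)
            if hi - lo < nz // 4:
                continue
            a = profiles[i, :, lo - lag : hi - lag]
            b = ref[:, lo:hi]
            costs[j] = np.nanmean((a - b) ** 2)
        if np.all(np.isnan(costs)):
            raise AlignmentError("profiles do not overlap")
        jbest = int(np.nanargmin(costs))
        finite = np.isfinite(costs)
        lag_refined = _parabolic_refine(
            lags[finite].astype(float), costs[finite], int(np.nonzero(finite)[0].tolist().index(jbest))
        ) if finite.sum() >= 3 else float(lags[jbest])
        # positive offset = bead i's features sit at larger z than the
        # reference bead's (best-matching lag is the negative of that shift)
        offsets[i] = -lag_refined * dz
        for k in range(n_planes):
            aligned[i, k] = np.interp(
                z_grid, z_grid - offsets[i], profiles[i, k], left=np.nan, right=np.nan
            )
    return aligned, offsets


def build_radius_calibration(
    profiles: np.ndarray,
    piezo_z: np.ndarray,
    smooth_window_um: float = 0.5,
    pixel_pitch: float = 1.0,
    align: bool = True,
) -> RadiusCalibration:
    """Average per-bead radius profiles into a radius-vs-z calibration.

    ``profiles``: (n_beads, n_planes, nz) radii in px on the ``piezo_z`` grid.
    Beads are z-aligned by least-mean-square profile matching, averaged,
    smoothed by a centered moving average (default window 0.5 µm), and the
    pointwise spread across beads is propagated to a z-precision via
    ``sigma_z = sigma_r / |dR/dz|``.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim == 2:
        profiles = profiles[None]
    piezo_z = np.asarray(piezo_z, dtype=float)
    if align and profiles.shape[0] > 1:
        aligned, _ = align_profiles(profiles, piezo_z)
    else:
        aligned = profiles
    mean_r = np.nanmean(aligned, axis=0)
    with np.errstate(invalid="ignore"):
        sigma_r = (
            np.nanstd(aligned, axis=0, ddof=0)
            if profiles.shape[0] > 1
            else np.zeros_like(mean_r)
        )
    dz = float(piezo_z[1] - piezo_z[0])
    window = max(int(round(smooth_window_um / dz)), 1)
    smooth = np.stack([_moving_average(row, window) for row in mean_r])
    sigma_r_s = np.stack([_moving_average(row, window) for row in sigma_r])
    slope = np.gradient(smooth, piezo_z, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_z = np.where(slope != 0, np.abs(sigma_r_s / slope), np.inf)
    sigma_z[sigma_r_s == 0] = 0.0
    return RadiusCalibration(piezo_z, smooth, sigma_r_s, sigma_z, pixel_pitch)


def predict_z_precision(
    calibration: RadiusCalibration, planes: list[int] | None = None
) -> tuple[np.ndarray, float]:
    """Combined z-precision: pointwise best (minimum) sigma_z over the planes.

    Returns (sigma_z array on the calibration z grid, mean over the depth).
    """
    if planes is None:
        planes = list(range(calibration.n_planes))
    if not planes:
        raise ValueError("need at least one plane")
    combined = np.min(calibration.sigma_z[planes], axis=0)
    finite = combined[np.isfinite(combined)]
    mean = float(finite.mean()) if finite.size else float("inf")
    return combined, mean


# --------------------------------------------------------------------------
# z inference
# --------------------------------------------------------------------------


@dataclass
class ZInference:
    """Outcome of cross-plane z inference for one detection."""

    z: float = float("nan")
    sigma_z: float = float("nan")
    planes_used: tuple[int, ...] = ()
    candidates: dict = field(default_factory=dict)  # plane -> [z, ...]
    excluded: bool = False
    reason: str = ""
    ambiguous: bool = False
    boundary: bool = False


def _difference_minima(
    r_meas: float, curve: np.ndarray, z_grid: np.ndarray
) -> tuple[list[float], bool, list[float]]:
    """Candidate z-positions: local minima of |r_meas - R(z)|.

    Returns up to two refined minima (one above, one below the focus), their
    difference-function depths, and a flag for minima sitting on the grid
    boundary (focus ambiguity not bracketed). If the measured radius lies
    below the curve's minimum the single global minimum is returned.
    """
    diff = np.abs(curve - r_meas)
    interior = np.nonzero(
        (diff[1:-1] <= diff[:-2]) & (diff[1:-1] <= diff[2:])
    )[0] + 1
    at_edge = False
    candidates: list[tuple[float, float, bool]] = []
    for i in interior:
        z_ref = _parabolic_refine(z_grid, diff, int(i))
        candidates.append((diff[i], z_ref, False))
    for i in (0, len(diff) - 1):
        if (i == 0 and diff[0] < diff[1]) or (
            i == len(diff) - 1 and diff[-1] < diff[-2]
        ):
            candidates.append((diff[i], float(z_grid[i]), True))
    candidates.sort(key=lambda c: c[0])
    # keep the two deepest minima, de-duplicated
    kept: list[float] = []
    depths: list[float] = []
    for depth, z, edge in candidates:
        if all(abs(z - other) > 2 * (z_grid[1] - z_grid[0]) for other in kept):
            kept.append(z)
            depths.append(float(depth))
            at_edge |= edge
        if len(kept) == 2:
            break
    return kept, at_edge, depths


def select_min_std_combination(
    candidates: dict[int, list[float]],
    sigma_at,
) -> tuple[dict[int, float], float, float, int]:
    """Pick one candidate per plane minimizing the standard deviation.

    ``sigma_at(plane, z)`` supplies the predicted precision used both for the
    tie-break (smaller precision at the combination mean wins) and for the
    final selection: the returned z is the member from the plane with the
    smallest predicted sigma_z. Returns (chosen z per plane, final z,
    final sigma_z, final plane).
    """
    planes = sorted(candidates)
    best = None
    for combo in itertools.product(*(candidates[p] for p in planes)):
        arr = np.asarray(combo)
        spread = float(arr.std())
        mean_z = float(arr.mean())
        sigmas = [float(sigma_at(p, z)) for p, z in zip(planes, combo)]
        tie = min(float(sigma_at(p, mean_z)) for p in planes)
        key = (spread, tie)
        if best is None or key < best[0]:
            best = (key, dict(zip(planes, combo)), sigmas)
    assert best is not None
    _, chosen, sigmas = best
    i_best = int(np.argmin(sigmas))
    plane_best = planes[i_best]
    return chosen, float(chosen[plane_best]), float(sigmas[i_best]), plane_best


def infer_bead_z(
    fits: list[CircleFitResult | None],
    calibration: RadiusCalibration,
    r2_min: float = 0.8,
    depth_sigma_factor: float = 5.0,
    depth_floor_px: float = 0.3,
) -> ZInference:
    """Infer the z-position of a bead from its per-plane circle fits.

    Planes with missing/invalid fits or ``r2 <= r2_min`` are discarded; fewer
    than two remaining planes excludes the detection (with the single plane's
    two candidates reported as ambiguous). Otherwise the minimum-standard-
    deviation candidate combination across planes fixes z, reported from the
    plane with the best predicted precision at that position.

    Candidates whose difference-function depth exceeds
    ``max(depth_floor_px, depth_sigma_factor * sigma_R)`` are inconsistent
    with the measured radius (this arises when the true mirror position lies
    outside the calibrated range and the minimum is clipped to the grid edge)
    and are dropped, along with planes retaining no consistent candidate.
    """
    valid_planes = [
        k
        for k, f in enumerate(fits)
        if f is not None and f.valid and np.isfinite(f.radius) and f.r2 > r2_min
    ]
    candidates: dict[int, list[float]] = {}
    boundary = False
    for k in valid_planes:
        cands, at_edge, depths = _difference_minima(
            fits[k].radius, calibration.radius[k], calibration.z_grid
        )
        kept = []
        for z, depth in zip(cands, depths):
            i = int(np.argmin(np.abs(calibration.z_grid - z)))
            tol = max(depth_floor_px, depth_sigma_factor * calibration.sigma_r[k, i])
            if depth <= tol:
                kept.append(z)
        cands = kept
        boundary |= at_edge
        if cands:
            candidates[k] = cands
    if len(candidates) < 2:
        inf = ZInference(
            excluded=True,
            reason="insufficient valid planes",
            candidates={k: list(v) for k, v in candidates.items()},
            boundary=boundary,
        )
        if len(candidates) == 1:
            inf.ambiguous = True
        return inf
    chosen, z_final, sigma_final, _ = select_min_std_combination(
        candidates, calibration.sigma_z_at
    )
    return ZInference(
        z=z_final,
        sigma_z=sigma_final,
        planes_used=tuple(sorted(chosen)),
        candidates={k: list(v) for k, v in candidates.items()},
        boundary=boundary,
    )


# --------------------------------------------------------------------------
# track linking
# --------------------------------------------------------------------------


@dataclass
class BeadTrack:
    """Time-ordered 3D positions sharing one identity."""

    track_id: int
    frames: np.ndarray  # (n,) int
    positions: np.ndarray  # (n, 3) µm

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def displacements(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)


def link_tracks(
    positions_per_frame: list[np.ndarray], max_dist: float = 1.5
) -> list[BeadTrack]:
    """Greedy nearest-neighbor frame-to-frame linking.

    Candidate links between consecutive frames are accepted in order of
    ascending 3D distance; links at or beyond ``max_dist`` (µm) are forbidden
    and unlinked detections start new tracks. No gap closing.
    """
    tracks: list[list[tuple[int, np.ndarray]]] = []
    open_tracks: dict[int, int] = {}  # detection index in prev frame -> track idx
    for t, pos in enumerate(positions_per_frame):
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        if pos.size == 0:
            open_tracks = {}
            continue
        new_open: dict[int, int] = {}
        if open_tracks:
            prev_idx = list(open_tracks)
            prev_pos = np.stack(
                [tracks[open_tracks[i]][-1][1] for i in prev_idx]
            )
            d = np.linalg.norm(prev_pos[:, None] - pos[None, :], axis=2)
            pairs = sorted(
                (
                    (d[a, b], a, b)
                    for a in range(len(prev_idx))
                    for b in range(len(pos))
                    if d[a, b] < max_dist
                )
            )
            used_prev: set[int] = set()
            used_cur: set[int] = set()
            for dist, a, b in pairs:
                if a in used_prev or b in used_cur:
                    continue
                used_prev.add(a)
                used_cur.add(b)
                ti = open_tracks[prev_idx[a]]
                tracks[ti].append((t, pos[b]))
                new_open[b] = ti
        for b in range(len(pos)):
            if b not in new_open:
                tracks.append([(t, pos[b])])
                new_open[b] = len(tracks) - 1
        open_tracks = new_open
    return [
        BeadTrack(
            i,
            np.array([f for f, _ in tr], dtype=int),
            np.stack([p for _, p in tr]),
        )
        for i, tr in enumerate(tracks)
    ]
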