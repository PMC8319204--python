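"""Flagellar centerline tracing and z reconstruction from multifocal frames.

The centerline is traced in 2D on the sharpest of the four plane images
(blur, Li threshold, skeletonize, longest path, spline resampling at a fixed
arc-length pitch). At every arc-length position a Gaussian is fitted to the
intensity profile normal to the flagellum in each plane; the fitted widths are
converted to z through a calibrated width-vs-(arc length, defocus) map using
the same two-candidate / minimum-standard-deviation scheme as the bead
localizer. An independent intensity-based z estimate fits the dependence of
the interpolated flagellar intensity on plane focal position.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import splev, splprep
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.filters import threshold_li
from skimage.morphology import skeletonize

from mfi3d.bead3d import select_min_std_combination
from mfi3d.frame import N_PLANES, MultifocalFrame
from mfi3d.optics_forward import DEFAULT_ARC_PITCH_UM


class NoFlagellumError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# sharpest plane
# --------------------------------------------------------------------------


def select_sharpest_plane(
    frame: MultifocalFrame, roi: tuple[slice, slice] | None = None
) -> int:
    """Plane index with the highest intensity standard deviation in the ROI.

    Ties break to the lowest index; the criterion is invariant to uniform
    intensity offsets.
    """
    stds = []
    for p in frame.planes:
        sub = p if roi is None else p[roi]
        if sub.size == 0:
            raise ValueError("empty ROI")
        stds.append(sub.std())
    return int(np.argmax(stds))


# --------------------------------------------------------------------------
# 2D centerline
# --------------------------------------------------------------------------


@dataclass
class FlagellumTrace2D:
    """Arc-length-parameterized 2D centerline (head at s = 0)."""

    points_px: np.ndarray  # (n, 2) as (x, y), subpixel
    s: np.ndarray  # (n,) arc length µm, strictly increasing from 0
    pixel_pitch: float  # µm/px
    source_plane: int = 0
    widths: np.ndarray | None = None  # (4, n) µm, filled by measure_width_profile
    peak_intensities: np.ndarray | None = None  # (4, n)
    width_flags: np.ndarray | None = None  # (4, n) bool, True = usable

    @property
    def length(self) -> float:
        return float(self.s[-1])

    @property
    def tangents(self) -> np.ndarray:
        t = np.gradient(self.points_px, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    @property
    def normals(self) -> np.ndarray:
        t = self.tangents
        return np.column_stack([-t[:, 1], t[:, 0]])


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path through a skeleton, as (n, 2) (row, col)."""
    coords = np.column_stack(np.nonzero(skel))
    if coords.size == 0:
        raise NoFlagellumError("empty skeleton")
    index = {tuple(c): i for i, c in enumerate(coords)}
    neighbors: list[list[int]] = [[] for _ in coords]
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, (r, c) in enumerate(coords):
        for dr, dc in offs:
            j = index.get((r + dr, c + dc))
            if j is not None:
                neighbors[i].append(j)

    def bfs(start: int) -> tuple[int, dict[int, int]]:
        prev = {start: -1}
        queue = deque([start])
        last = start
        while queue:
            u = queue.popleft()
            last = u
            for v in neighbors[u]:
                if v not in prev:
                    prev[v] = u
                    queue.append(v)
        return last, prev

    far, _ = bfs(0)
    end, prev = bfs(far)
    path = []
    node = end
    while node != -1:
        path.append(node)
        node = prev[node]
    return coords[path[::-1]]


def extract_centerline_2d(
    image: np.ndarray,
    pixel_pitch: float,
    arc_pitch_um: float = DEFAULT_ARC_PITCH_UM,
    blur_sigma_px: float = 2.0,
    min_length_um: float = 20.0,
    spline_smooth_px2: float = 0.25,
    source_plane: int = 0,
    head_hint: tuple[float, float] | None = None,
) -> FlagellumTrace2D:
    """Trace the dominant filament in a single-plane image.

    Pipeline: Gaussian blur, Li threshold, skeletonize, keep the longest
    skeleton path, fit a smoothing spline and resample at a fixed arc-length
    pitch. The head end is placed at s = 0: the endpoint nearer ``head_hint``
    (px) when given — e.g. the previous frame's head — otherwise the endpoint
    with the larger local integrated intensity. Raises
    :class:`NoFlagellumError` if no sufficiently long skeleton is found.
    """
    image = np.asarray(image, dtype=float)
    blurred = gaussian_filter(image, blur_sigma_px)
    mask = blurred > threshold_li(blurred)
    if not mask.any():
        raise NoFlagellumError("nothing above threshold")
    skel = skeletonize(mask)
    path_rc = _longest_skeleton_path(skel)
    if len(path_rc) * pixel_pitch < min_length_um:
        raise NoFlagellumError(
            f"longest skeleton path shorter than {min_length_um} µm"
        )
    xy = path_rc[:, ::-1].astype(float)  # (x, y)
    # subsample to decorrelate integer-pixel jitter before spline fitting
    step = max(len(xy) // 200, 1)
    knots = xy[::step]
    if not np.array_equal(knots[-1], xy[-1]):
        knots = np.vstack([knots, xy[-1]])
    tck, _ = splprep(
        [knots[:, 0], knots[:, 1]], s=spline_smooth_px2 * len(knots), k=3
    )
    dense_u = np.linspace(0.0, 1.0, 10 * len(knots))
    dx, dy = splev(dense_u, tck)
    dense = np.column_stack([dx, dy])
    # skeletonization erodes the filament tips by roughly the blur radius;
    # extend both ends along the end tangent up to the 50% edge-spread point
    # of the local ridge plateau (for a blurred intensity step along the
    # ridge, that half-maximum sits at the physical tip)
    step_px = arc_pitch_um / pixel_pitch

    def extend(end, prev, max_steps=30):
        tangent = end - prev
        tangent = tangent / np.linalg.norm(tangent)
        xi, yi = int(round(end[0])), int(round(end[1]))
        plateau = blurred[
            max(yi - 1, 0) : yi + 2, max(xi - 1, 0) : xi + 2
        ].max()
        extra = []
        p = end.copy()
        for _ in range(max_steps):
            p = p + tangent * step_px
            xi, yi = int(round(p[0])), int(round(p[1]))
            if not (0 <= yi < image.shape[0] and 0 <= xi < image.shape[1]):
                break
            if blurred[yi, xi] <= 0.5 * plateau:
                break
            extra.append(p.copy())
        return extra

    head_ext = extend(dense[0], dense[5])[::-1]
    tail_ext = extend(dense[-1], dense[-6])
    if head_ext or tail_ext:
        dense = np.vstack([np.asarray(head_ext).reshape(-1, 2), dense,
                           np.asarray(tail_ext).reshape(-1, 2)])
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1) * pixel_pitch
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total < min_length_um:
        raise NoFlagellumError("traced filament too short")
    s_out = np.arange(0.0, total, arc_pitch_um)
    pts = np.column_stack(
        [np.interp(s_out, arc, dense[:, 0]), np.interp(s_out, arc, dense[:, 1])]
    )
    if head_hint is not None:
        hint = np.asarray(head_hint, dtype=float)
        if np.linalg.norm(pts[-1] - hint) < np.linalg.norm(pts[0] - hint):
            pts = pts[::-1].copy()
    else:
        # orient: head = endpoint with larger local integrated intensity
        r = max(int(3.0 / pixel_pitch), 2)

        def end_mass(p):
            x, y = int(round(p[0])), int(round(p[1]))
            y0, y1 = max(y - r, 0), min(y + r + 1, image.shape[0])
            x0, x1 = max(x - r, 0), min(x + r + 1, image.shape[1])
            return blurred[y0:y1, x0:x1].sum()

        if end_mass(pts[-1]) > end_mass(pts[0]):
            pts = pts[::-1].copy()
    return FlagellumTrace2D(pts, s_out, pixel_pitch, source_plane)


# --------------------------------------------------------------------------
# width / intensity measurement
# --------------------------------------------------------------------------


def fit_gaussian_profiles(
    profiles: np.ndarray, x: np.ndarray, n_iter: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 1D Gaussian fits (amplitude, center, sigma, offset).

    Moment-based initialization followed by damped Gauss-Newton iterations,
    solved as a batch of 4x4 normal-equation systems. Returns
    (params (n, 4), flags (n,)) where a flag marks a usable fit (clear
    amplitude above residual noise, center inside the window, sane sigma).
    """
    y = np.asarray(profiles, dtype=float)
    n, m = y.shape
    off = y.min(axis=1)
    amp = y.max(axis=1) - off
    p = np.clip(y - off[:, None], 0.0, None)
    wsum = p.sum(axis=1) + 1e-12
    mu = (p * x).sum(axis=1) / wsum
    var = (p * (x - mu[:, None]) ** 2).sum(axis=1) / wsum
    sigma = np.sqrt(np.clip(var, 0.05, None))
    params = np.column_stack([amp, mu, sigma, off])
    lam = 1e-3
    for _ in range(n_iter):
        a, c, s, o = params.T
        dxn = (x[None, :] - c[:, None]) / s[:, None]
        e = np.exp(-0.5 * dxn**2)
        model = a[:, None] * e + o[:, None]
        r = model - y
        j = np.empty((n, m, 4))
        j[:, :, 0] = e
        j[:, :, 1] = a[:, None] * e * dxn / s[:, None]
        j[:, :, 2] = a[:, None] * e * dxn**2 / s[:, None]
        j[:, :, 3] = 1.0
        jtj = np.einsum("nmi,nmj->nij", j, j)
        jtj += lam * np.eye(4)[None]
        jtr = np.einsum("nmi,nm->ni", j, r)
        try:
            delta = np.linalg.solve(jtj, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        params = params - delta
        params[:, 2] = np.clip(np.abs(params[:, 2]), 0.05, None)
    a, c, s, o = params.T
    dxn = (x[None, :] - c[:, None]) / s[:, None]
    resid = a[:, None] * np.exp(-0.5 * dxn**2) + o[:, None] - y
    rstd = resid.std(axis=1)
    half = 0.5 * (x[-1] - x[0])
    flags = (
        (a > 4.0 * rstd)
        & (a > 0)
        & (np.abs(c - x.mean()) < 0.8 * half)
        & (s < 0.8 * half)
        & (s > 0.1)
    )
    return params, flags


def measure_width_profile(
    frame: MultifocalFrame,
    trace: FlagellumTrace2D,
    half_width_px: float = 12.0,
    n_samples: int = 25,
) -> FlagellumTrace2D:
    """Fit Gaussians normal to the centerline in all four planes.

    Samples the intensity along the normal at every arc-length point
    (bilinear interpolation, ±``half_width_px``), fits a 1D Gaussian per
    point and plane, and stores widths (µm, Gaussian sigma), peak intensities
    and per-point validity flags on the trace. Returns the same trace.
    """
    offsets = np.linspace(-half_width_px, half_width_px, n_samples)
    normals = trace.normals
    n_pts = len(trace.points_px)
    widths = np.full((N_PLANES, n_pts), np.nan)
    peaks = np.full((N_PLANES, n_pts), np.nan)
    flags = np.zeros((N_PLANES, n_pts), dtype=bool)
    # sample coordinates: (n_pts, n_samples)
    sx = trace.points_px[:, 0:1] + normals[:, 0:1] * offsets[None, :]
    sy = trace.points_px[:, 1:2] + normals[:, 1:2] * offsets[None, :]
    for k in range(N_PLANES):
        prof = map_coordinates(
            frame.planes[k], [sy.ravel(), sx.ravel()], order=1, mode="nearest"
        ).reshape(n_pts, n_samples)
        params, ok = fit_gaussian_profiles(prof, offsets)
        widths[k] = params[:, 2] * trace.pixel_pitch
        peaks[k] = params[:, 0] + params[:, 3]
        flags[k] = ok
    trace.widths = widths
    trace.peak_intensities = peaks
    trace.width_flags = flags
    return trace


def widths_on_grid(trace: FlagellumTrace2D, s_grid: np.ndarray) -> np.ndarray:
    """Interpolate a trace's per-plane widths onto a common arc-length grid.

    Flagged-out or missing points become NaN; so do grid positions outside
    the traced range.
    """
    if trace.widths is None:
        raise ValueError("run measure_width_profile first")
    out = np.full((N_PLANES, len(s_grid)), np.nan)
    for k in range(N_PLANES):
        w = trace.widths[k].copy()
        if trace.width_flags is not None:
            w[~trace.width_flags[k]] = np.nan
        good = np.isfinite(w)
        if good.sum() < 2:
            continue
        out[k] = np.interp(
            s_grid, trace.s[good], w[good], left=np.nan, right=np.nan
        )
        # do not extrapolate across large flagged gaps
        out[k][
            (s_grid < trace.s[good][0]) | (s_grid > trace.s[good][-1])
        ] = np.nan
    return out


# --------------------------------------------------------------------------
# width calibration map
# --------------------------------------------------------------------------


@dataclass
class WidthCalibrationMap:
    """Flagellar width as a function of (arc length, defocus) per plane.

    ``width[k, i, j]`` is the Gaussian width (µm) at arc length ``s_grid[i]``
    and z-offset ``dz_grid[j]`` relative to plane k's focus; NaN where the
    calibration stacks gave no data.
    """

    s_grid: np.ndarray  # (ns,) µm
    dz_grid: np.ndarray  # (ndz,) µm
    width: np.ndarray  # (4, ns, ndz) µm
    spread: np.ndarray | None = None  # across-cell sd, same shape

    def curve_at(self, plane: int, s: float) -> np.ndarray:
        """Width-vs-defocus curve at the nearest calibrated arc length."""
        i = int(np.clip(np.searchsorted(self.s_grid, s), 0, len(self.s_grid) - 1))
        if i > 0 and abs(self.s_grid[i - 1] - s) < abs(self.s_grid[i] - s):
            i -= 1
        return self.width[plane, i]


def _nan_median_filter(arr: np.ndarray, size: int) -> np.ndarray:
    """Median filter that ignores NaNs (and preserves NaN holes)."""
    import warnings

    pad = size // 2
    padded = np.pad(arr, pad, mode="edge")
    win = sliding_window_view(padded, (size, size))[: arr.shape[0], : arr.shape[1]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmedian(win.reshape(*arr.shape, -1), axis=-1)
    out[np.isnan(arr)] = np.nan
    return out


def build_width_calibration(
    cells: list[np.ndarray],
    piezo_z: np.ndarray,
    plane_offsets: np.ndarray,
    s_grid: np.ndarray,
    median_size: int = 6,
) -> WidthCalibrationMap:
    """Accumulate per-cell width measurements into a calibration map.

    ``cells``: one array per calibration cell of shape (nz, 4, ns) — widths
    (µm) measured at every piezo step, plane, and arc-length position on the
    common ``s_grid``; NaN marks failed fits. The per-plane defocus of step j
    is ``piezo_z[j] - plane_offsets[k]``. Cell maps are averaged and smoothed
    with a ``median_size`` x ``median_size`` median filter.
    """
    piezo_z = np.asarray(piezo_z, dtype=float)
    plane_offsets = np.asarray(plane_offsets, dtype=float)
    dz_step = float(piezo_z[1] - piezo_z[0])
    dz_min = piezo_z[0] - plane_offsets.max()
    dz_max = piezo_z[-1] - plane_offsets.min()
    dz_grid = np.arange(dz_min, dz_max + dz_step / 2, dz_step)
    ns = len(s_grid)
    acc = np.full((len(cells), N_PLANES, ns, len(dz_grid)), np.nan)
    for c, widths in enumerate(cells):
        widths = np.asarray(widths, dtype=float)
        if widths.shape[1:] != (N_PLANES, ns):
            raise ValueError("cell array must have shape (nz, 4, len(s_grid))")
        for k in range(N_PLANES):
            dz = piezo_z - plane_offsets[k]
            j = np.rint((dz - dz_grid[0]) / dz_step).astype(int)
            ok = (j >= 0) & (j < len(dz_grid))
            acc[c, k][:, j[ok]] = widths[ok, k, :].T
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(acc, axis=0)
        spread = np.nanstd(acc, axis=0) if len(cells) > 1 else None
    if not np.any(np.isfinite(mean)):
        raise ValueError("no overlapping calibration data")
    smoothed = np.stack(
        [_nan_median_filter(mean[k], median_size) for k in range(N_PLANES)]
    )
    return WidthCalibrationMap(np.asarray(s_grid, float), dz_grid, smoothed, spread)


# --------------------------------------------------------------------------
# z inference
# --------------------------------------------------------------------------


def _width_candidates(
    w_meas: float, curve: np.ndarray, dz_grid: np.ndarray
) -> tuple[list[float], bool]:
    """Up to two defocus candidates from inverting one width-vs-dz curve."""
    from mfi3d.bead3d import _difference_minima

    finite = np.isfinite(curve)
    if finite.sum() < 3:
        return [], False
    idx = np.nonzero(finite)[0]
    lo, hi = idx[0], idx[-1] + 1
    sub = curve[lo:hi]
    if not np.all(np.isfinite(sub)):
        sub = np.interp(
            dz_grid[lo:hi], dz_grid[lo:hi][np.isfinite(sub)], sub[np.isfinite(sub)]
        )
    flagged = w_meas < np.nanmin(sub)
    if flagged:
        # width below the calibrated minimum: single nearest-grid candidate
        grid = dz_grid[lo:hi]
        return [float(grid[int(np.argmin(sub))])], True
    cands, _, _ = _difference_minima(w_meas, sub, dz_grid[lo:hi])
    return cands, flagged


def infer_flagellar_z(
    trace: FlagellumTrace2D,
    width_map: WidthCalibrationMap,
    plane_offsets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Width-based z per arc-length point.

    For every point and plane, inverting the calibrated width-vs-defocus
    curve yields two candidate z-positions; the cross-plane combination with
    the minimum standard deviation is selected and its members averaged.
    Returns (z (n,), flags (n,)) with NaN/False where fewer than two planes
    contributed.
    """
    if trace.widths is None:
        raise ValueError("run measure_width_profile first")
    plane_offsets = np.asarray(plane_offsets, dtype=float)
    n_pts = len(trace.points_px)
    z_out = np.full(n_pts, np.nan)
    ok = np.zeros(n_pts, dtype=bool)
    for i in range(n_pts):
        candidates: dict[int, list[float]] = {}
        for k in range(N_PLANES):
            if trace.width_flags is not None and not trace.width_flags[k, i]:
                continue
            w = trace.widths[k, i]
            if not np.isfinite(w):
                continue
            curve = width_map.curve_at(k, trace.s[i])
            cands, _ = _width_candidates(w, curve, width_map.dz_grid)
            if cands:
                candidates[k] = [plane_offsets[k] + dz for dz in cands]
        if len(candidates) < 2:
            continue
        chosen, _, _, _ = select_min_std_combination(
            candidates, lambda p, z: 1.0
        )
        z_out[i] = float(np.mean(list(chosen.values())))
        ok[i] = True
    return z_out, ok


def infer_z_from_intensity(
    trace: FlagellumTrace2D,
    frame: MultifocalFrame,
    plane_offsets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity-based z per arc-length point.

    The flagellar intensity at a point, interpolated in each plane, peaks in
    the plane whose focus is nearest; fitting a Gaussian (parabola in log
    intensity) to the four (focal position, intensity) pairs gives the
    z-position as the fitted center. Points with non-concave or out-of-span
    profiles are flagged unreliable. Returns (z (n,), flags (n,)).
    """
    offsets = (
        np.asarray(plane_offsets, dtype=float)
        if plane_offsets is not None
        else frame.plane_offsets
    )
    n_pts = len(trace.points_px)
    intens = np.empty((N_PLANES, n_pts))
    for k in range(N_PLANES):
        intens[k] = map_coordinates(
            frame.planes[k],
            [trace.points_px[:, 1], trace.points_px[:, 0]],
            order=1,
            mode="nearest",
        )
    z_out = np.full(n_pts, np.nan)
    ok = np.zeros(n_pts, dtype=bool)
    floor = max(intens.max() * 1e-6, 1e-12)
    logs = np.log(np.clip(intens, floor, None))
    # parabola fit in log space: log I = a z^2 + b z + c; center = -b / 2a
    design = np.column_stack([offsets**2, offsets, np.ones_like(offsets)])
    coef, *_ = np.linalg.lstsq(design, logs, rcond=None)
    a, b = coef[0], coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        center = -b / (2.0 * a)
    span = offsets.max() - offsets.min()
    good = (
        (a < 0)
        & (center > offsets.min() - 0.5 * span)
        & (center < offsets.max() + 0.5 * span)
    )
    z_out[good] = center[good]
    ok[good] = True
    return z_out, ok


def smooth_arclength(
    z: np.ndarray,
    arc_pitch_um: float = DEFAULT_ARC_PITCH_UM,
    median_window_um: float = 2.2,
    mean_window_um: float = 2.2,
) -> np.ndarray:
    """Per-timepoint z(s) smoothing: moving median, then moving average.

    Windows are centered and shrink at the endpoints; NaNs are ignored where
    possible and propagated where a window holds no data.
    """
    z = np.asarray(z, dtype=float)
    out = z.copy()
    for window_um, fn in (
        (median_window_um, np.nanmedian),
        (mean_window_um, np.nanmean),
    ):
        w = max(int(round(window_um / arc_pitch_um)), 1)
        half = w // 2
        src = out
        out = np.full_like(src, np.nan)
        for i in range(len(src)):
            seg = src[max(i - half, 0) : i + half + 1]
            if np.any(np.isfinite(seg)):
                with np.errstate(all="ignore"):
                    out[i] = fn(seg)
    return out


# --------------------------------------------------------------------------
# time-series container / high-level reconstruction
# --------------------------------------------------------------------------


@dataclass
class FlagellumTrace3D:
    """Time-resolved 3D centerline on a common arc-length grid."""

    s: np.ndarray  # (n_s,) µm
    positions: np.ndarray  # (n_t, n_s, 3) µm
    timestamps: np.ndarray  # (n_t,) s
    z_method: str = "width"
    flags: np.ndarray | None = None  # (n_t, n_s) bool

    def to_dataframe(self):
        import pandas as pd

        n_t, n_s, _ = self.positions.shape
        t = np.repeat(self.timestamps, n_s)
        s = np.tile(self.s, n_t)
        flat = self.positions.reshape(-1, 3)
        return pd.DataFrame(
            {
                "t_s": t,
                "s_um": s,
                "x_um": flat[:, 0],
                "y_um": flat[:, 1],
                "z_um": flat[:, 2],
            }
        )


def reconstruct_frame(
    frame: MultifocalFrame,
    width_map: WidthCalibrationMap,
    z_fusion: str = "width",
    head_region_um: float = 10.0,
    **centerline_kwargs,
) -> tuple[FlagellumTrace2D, np.ndarray, np.ndarray]:
    """Full single-frame reconstruction.

    Traces the centerline on the sharpest plane, measures widths, infers z
    (width-based, optionally fused with the intensity-based estimate by an
    unweighted mean of unflagged values) and smooths z along arc length.
    Returns (trace2d, z (n,), reliable flags (n,)); points in the head/neck
    region (s < ``head_region_um``) keep their values but are marked
    low-confidence in the returned flags only if they were already flagged.
    """
    sharp = select_sharpest_plane(frame)
    trace = extract_centerline_2d(
        frame.planes[sharp],
        frame.pixel_pitch,
        source_plane=sharp,
        **centerline_kwargs,
    )
    measure_width_profile(frame, trace)
    z_w, ok_w = infer_flagellar_z(trace, width_map, frame.plane_offsets)
    if z_fusion == "width":
        z, ok = z_w, ok_w
    else:
        z_i, ok_i = infer_z_from_intensity(trace, frame)
        both = np.stack([np.where(ok_w, z_w, np.nan), np.where(ok_i, z_i, np.nan)])
        with np.errstate(all="ignore"):
            z = np.nanmean(both, axis=0)
        ok = ok_w | ok_i
    z = smooth_arclength(z)
    return trace, z, ok


def reconstruct_video(
    frames: list[MultifocalFrame],
    width_map: WidthCalibrationMap,
    frame_rate: float = 500.0,
    **kwargs,
) -> FlagellumTrace3D:
    """Reconstruct a time series onto the common arc-length grid of the
    shortest trace; points without a reliable z estimate are NaN in z."""
    traces = []
    zs = []
    oks = []
    head_hint = kwargs.pop("head_hint", None)
    for frame in frames:
        trace, z, ok = reconstruct_frame(
            frame, width_map, head_hint=head_hint, **kwargs
        )
        head_hint = tuple(trace.points_px[0])
        traces.append(trace)
        zs.append(z)
        oks.append(ok)
    n_s = min(len(t.s) for t in traces)
    s = traces[0].s[:n_s]
    n_t = len(traces)
    positions = np.full((n_t, n_s, 3), np.nan)
    flags = np.zeros((n_t, n_s), dtype=bool)
    for i, (trace, z, ok) in enumerate(zip(traces, zs, oks)):
        positions[i, :, 0] = trace.points_px[:n_s, 0] * trace.pixel_pitch
        positions[i, :, 1] = trace.points_px[:n_s, 1] * trace.pixel_pitch
        positions[i, :, 2] = z[:n_s]
        flags[i] = ok[:n_s]
    timestamps = np.arange(n_t) / frame_rate
    return FlagellumTrace3D(s, positions, timestamps, flags=flags)
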