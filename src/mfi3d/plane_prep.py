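"""Preparation of raw four-view recordings.

Covers intensity normalization across planes (flat-field from a blank frame),
co-registration of the four plane images onto plane 1 (translation +
isotropic scale estimated from skeletonized calibration-grid images),
interplane-distance estimation from a focus sweep, and a variance-based
extended-depth-of-field composite with its argmax-plane depth map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter
from scipy.spatial import cKDTree
from skimage.filters import threshold_li
from skimage.morphology import skeletonize
from skimage.transform import SimilarityTransform, warp

from mfi3d.frame import N_PLANES, MultifocalFrame


class InvalidMapError(ValueError):
    pass


class RegistrationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# intensity normalization
# --------------------------------------------------------------------------


@dataclass
class IntensityMap:
    """Per-plane fractional intensity relative to the global mean."""

    fractions: np.ndarray  # (4, H, W), all > 0, global mean ~ 1

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions <= 0):
            raise InvalidMapError("fractional intensities must be positive")


def build_intensity_map(
    blank_frame: MultifocalFrame, smooth_sigma_px: float = 5.0
) -> IntensityMap:
    """Fractional-intensity heatmap from a specimen-free recording.

    Each plane is smoothed and divided by the mean over all planes, so the
    map captures both vignetting within a plane and brightness differences
    between planes.
    """
    smoothed = np.stack(
        [gaussian_filter(p, smooth_sigma_px) for p in blank_frame.planes]
    )
    mean = smoothed.mean()
    if mean <= 0 or np.any(smoothed <= 0):
        raise InvalidMapError("blank frame must be strictly positive")
    return IntensityMap(smoothed / mean)


def normalize_planes(
    frame: MultifocalFrame, intensity_map: IntensityMap
) -> MultifocalFrame:
    """Divide every pixel by its fractional intensity value."""
    if intensity_map.fractions.shape != frame.planes.shape:
        raise InvalidMapError("intensity map shape does not match frame")
    out = frame.copy()
    out.planes = frame.planes / intensity_map.fractions
    return out


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------


@dataclass
class PlaneTransform:
    """Similarity transform mapping a plane's coordinates into plane 1."""

    scale: float = 1.0
    rotation: float = 0.0  # radians
    translation: tuple[float, float] = (0.0, 0.0)  # (tx, ty) px

    @property
    def is_identity(self) -> bool:
        return (
            self.scale == 1.0
            and self.rotation == 0.0
            and self.translation == (0.0, 0.0)
        )

    def to_skimage(self) -> SimilarityTransform:
        return SimilarityTransform(
            scale=self.scale,
            rotation=self.rotation,
            translation=self.translation,
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (x, y) point coordinates into plane-1 coordinates."""
        return self.to_skimage()(points)


@dataclass
class RegistrationModel:
    """Per-plane transforms (plane 1 fixed to identity) plus fit residuals."""

    transforms: list[PlaneTransform]
    residuals_px: list[float] = field(default_factory=lambda: [0.0] * N_PLANES)

    def __post_init__(self) -> None:
        if len(self.transforms) != N_PLANES:
            raise ValueError("need one transform per plane")
        if not self.transforms[0].is_identity:
            raise ValueError("plane 1 transform must be the identity")

    def to_json(self, path) -> None:
        payload = {
            "transforms": [
                {
                    "scale": t.scale,
                    "rotation": t.rotation,
                    "translation": list(t.translation),
                }
                for t in self.transforms
            ],
            "residuals_px": list(self.residuals_px),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RegistrationModel":
        with open(path) as fh:
            payload = json.load(fh)
        transforms = [
            PlaneTransform(t["scale"], t["rotation"], tuple(t["translation"]))
            for t in payload["transforms"]
        ]
        return cls(transforms, payload.get("residuals_px", [0.0] * N_PLANES))


def _skeleton_points(image: np.ndarray, border_px: int = 8) -> np.ndarray:
    """Li-threshold + skeletonize; returns (N, 2) array of (x, y) coords.

    Points within ``border_px`` of the image edge are dropped: warped planes
    lose content there, and unmatched border points bias the similarity fit.
    """
    thresh = threshold_li(image)
    mask = image > thresh
    if not mask.any():
        raise RegistrationError("empty segmentation")
    skel = skeletonize(mask)
    ys, xs = np.nonzero(skel)
    keep = (
        (xs >= border_px)
        & (xs < image.shape[1] - border_px)
        & (ys >= border_px)
        & (ys < image.shape[0] - border_px)
    )
    xs, ys = xs[keep], ys[keep]
    if xs.size == 0:
        raise RegistrationError("empty skeleton")
    return np.column_stack([xs, ys]).astype(float)


def _fit_similarity(
    src: np.ndarray, dst: np.ndarray, allow_rotation: bool
) -> tuple[float, float, np.ndarray]:
    """Closed-form LSQ similarity (scale[, rotation], translation) src -> dst."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    cs = src - mu_s
    cd = dst - mu_d
    if allow_rotation:
        # Umeyama
        cov = cd.T @ cs / len(src)
        u, dvals, vt = np.linalg.svd(cov)
        s = np.eye(2)
        if np.linalg.det(u) * np.linalg.det(vt) < 0:
            s[1, 1] = -1
        rot = u @ s @ vt
        var_s = (cs**2).sum() / len(src)
        scale = np.trace(np.diag(dvals) @ s) / var_s
        theta = float(np.arctan2(rot[1, 0], rot[0, 0]))
    else:
        scale = float((cs * cd).sum() / (cs**2).sum())
        theta = 0.0
        rot = np.eye(2)
    translation = mu_d - scale * (rot @ mu_s)
    return scale, theta, translation


def _intensity_refine(
    ref_img: np.ndarray,
    mov_img: np.ndarray,
    scale0: float,
    trans0: np.ndarray,
    margin: int = 10,
) -> tuple[float, np.ndarray]:
    """Refine (scale, tx, ty) by minimizing the interior-pixel MSE."""
    from scipy.optimize import minimize

    interior = (slice(margin, ref_img.shape[0] - margin),
                slice(margin, ref_img.shape[1] - margin))
    ref_sub = ref_img[interior]

    def cost(theta):
        s, tx, ty = theta
        tform = SimilarityTransform(scale=s, translation=(tx, ty))
        moved = warp(mov_img, tform.inverse, order=1, preserve_range=True)
        return float(np.mean((moved[interior] - ref_sub) ** 2))

    res = minimize(
        cost,
        x0=[scale0, trans0[0], trans0[1]],
        method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-8},
    )
    s, tx, ty = res.x
    return float(s), np.array([tx, ty])


def register_planes_from_grid(
    grid_frame: MultifocalFrame,
    allow_rotation: bool = False,
    max_iter: int = 20,
    tol_px: float = 0.01,
    intensity_refine: bool = True,
) -> RegistrationModel:
    """Estimate per-plane similarity transforms from a calibration grid.

    Each plane is segmented (Li threshold), skeletonized, and its skeleton is
    aligned to plane 1's by ICP-style nearest-neighbor iteration with a
    closed-form similarity fit (translation + isotropic scale by default).
    Skeleton rasterization limits that estimate to a few tenths of a pixel,
    so by default the parameters are refined by direct minimization of the
    inter-plane intensity MSE (disabled via ``intensity_refine=False``; the
    refinement does not support rotation).
    """
    from skimage.registration import phase_cross_correlation

    point_sets = [_skeleton_points(p) for p in grid_frame.planes]
    ref = point_sets[0]
    tree = cKDTree(ref)
    transforms: list[PlaneTransform] = [PlaneTransform()]
    residuals: list[float] = [0.0]
    for k in range(1, N_PLANES):
        pts = point_sets[k]
        # phase-correlation translation seed keeps the nearest-neighbor
        # matching on the right grid cell for shifts beyond half a period
        shift_rc, _, _ = phase_cross_correlation(
            grid_frame.planes[0], grid_frame.planes[k], upsample_factor=10
        )
        pts = pts + shift_rc[::-1]
        scale, theta, trans = 1.0, 0.0, np.zeros(2)
        moved = pts
        prev_shift = None
        for _ in range(max_iter):
            dists, idx = tree.query(moved)
            # trimmed matching: drop correspondences beyond 3x the median
            # distance (unpaired skeleton fragments would bias the fit)
            cutoff = max(3.0 * np.median(dists), 1.5)
            good = dists <= cutoff
            if good.sum() < 3:
                raise RegistrationError("too few skeleton correspondences")
            scale, theta, trans = _fit_similarity(
                pts[good], ref[idx[good]], allow_rotation
            )
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            new_moved = scale * pts @ rot.T + trans
            shift = float(np.mean(np.linalg.norm(new_moved - moved, axis=1)))
            moved = new_moved
            if prev_shift is not None and shift < tol_px:
                break
            prev_shift = shift
        dists, _ = tree.query(moved)
        # compose the phase-correlation seed into the reported transform so
        # it applies to unshifted plane-k coordinates
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        total_trans = scale * (rot @ shift_rc[::-1]) + trans
        if intensity_refine and not allow_rotation:
            scale, total_trans = _intensity_refine(
                grid_frame.planes[0], grid_frame.planes[k], scale, total_trans
            )
            tf = SimilarityTransform(scale=scale, translation=tuple(total_trans))
            moved2 = tf(point_sets[k])
            dists, _ = tree.query(moved2)
        transforms.append(PlaneTransform(scale, theta, tuple(total_trans)))
        residuals.append(float(np.mean(dists)))
    return RegistrationModel(transforms, residuals)


def apply_registration(
    frame: MultifocalFrame, model: RegistrationModel
) -> MultifocalFrame:
    """Resample planes 2-4 into plane-1 coordinates (bilinear)."""
    if len(model.transforms) != frame.planes.shape[0]:
        raise ValueError("model does not match frame")
    out = frame.copy()
    for k, tform in enumerate(model.transforms):
        if tform.is_identity:
            continue
        out.planes[k] = warp(
            frame.planes[k],
            tform.to_skimage().inverse,
            order=1,
            preserve_range=True,
        )
    return out


def invert_model(model: RegistrationModel) -> RegistrationModel:
    """Inverse transforms (useful for round-trip checks)."""
    inv = []
    for t in model.transforms:
        m = np.linalg.inv(t.to_skimage().params)
        tf = SimilarityTransform(matrix=m)
        inv.append(
            PlaneTransform(
                float(tf.scale), float(tf.rotation), tuple(tf.translation)
            )
        )
    return RegistrationModel(inv, model.residuals_px)


# --------------------------------------------------------------------------
# interplane distances
# --------------------------------------------------------------------------


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through (x, y) at indices i-1, i, i+1."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = 0.5 * (x[i + 1] - x[i - 1])
    return float(x[i] + np.clip(delta, -1, 1) * step)


def estimate_interplane_distances(
    zstack: list[MultifocalFrame], piezo_z: np.ndarray
) -> np.ndarray:
    """Per-plane focus positions from a piezo sweep; offsets relative to plane 1.

    Focus of a plane is the piezo position maximizing that plane image's
    intensity standard deviation, refined by a 3-point parabola. The estimate
    is invariant to stack ordering and uniform intensity scaling.
    """
    piezo_z = np.asarray(piezo_z, dtype=float)
    if len(zstack) != len(piezo_z):
        raise ValueError("zstack and piezo_z lengths differ")
    order = np.argsort(piezo_z)
    piezo_z = piezo_z[order]
    n_planes = zstack[0].planes.shape[0]
    sharpness = np.empty((n_planes, len(zstack)))
    for j, i in enumerate(order):
        for k in range(n_planes):
            sharpness[k, j] = zstack[i].planes[k].std()
    foci = np.empty(n_planes)
    for k in range(n_planes):
        i = int(np.argmax(sharpness[k]))
        if i in (0, len(piezo_z) - 1):
            warnings.warn(
                f"plane {k + 1}: sharpness maximum at stack boundary; "
                "focus not bracketed",
                stacklevel=2,
            )
        foci[k] = _parabolic_refine(piezo_z, sharpness[k], i)
    return foci - foci[0]


# --------------------------------------------------------------------------
# EDOF / depth map
# --------------------------------------------------------------------------


def edof_depth_map(
    frame: MultifocalFrame, window_px: int = 9, median_px: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Variance-based focus stacking.

    Per pixel and plane, sharpness is the local intensity variance in a
    ``window_px`` neighborhood; the depth map is the argmax plane index
    (ties break to the lowest index) and the EDOF image takes each pixel
    from its argmax plane. Optional median smoothing of the depth map.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    var = np.stack(
        [
            uniform_filter(p**2, window_px) - uniform_filter(p, window_px) ** 2
            for p in frame.planes
        ]
    )
    depth = np.argmax(var, axis=0)
    if median_px:
        from scipy.ndimage import median_filter

        depth = median_filter(depth, size=median_px)
    edof = np.take_along_axis(frame.planes, depth[None], axis=0)[0]
    return edof, depth
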