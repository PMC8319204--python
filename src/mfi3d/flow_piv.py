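"""Track-based 3D particle imaging velocimetry.

Instantaneous velocities of tracked tracer beads are voxel-averaged on a
regular grid (default 4 x 4 x 2 µm) to estimate the mean flow field; each
displacement's velocity is assigned to the voxel containing its midpoint.
Voxels without samples are empty, never zero-velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mfi3d.bead3d import BeadTrack


class EmptyFieldError(RuntimeError):
    pass


@dataclass
class FlowField:
    """Voxelized mean-velocity grid.

    ``velocity`` is (nx, ny, nz, 3) in µm/s with NaN in empty voxels;
    ``counts`` holds the number of velocity samples per voxel.
    """

    origin: np.ndarray  # (3,) µm, corner of voxel (0, 0, 0)
    spacing: np.ndarray  # (3,) µm
    velocity: np.ndarray  # (nx, ny, nz, 3)
    counts: np.ndarray  # (nx, ny, nz)

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=-1)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [
            self.origin[d] + (np.arange(self.counts.shape[d]) + 0.5) * self.spacing[d]
            for d in range(3)
        ]
        return tuple(axes)

    def to_dataframe(self):
        import pandas as pd

        ix, iy, iz = np.nonzero(self.counts)
        centers = [
            self.origin[d] + (idx + 0.5) * self.spacing[d]
            for d, idx in enumerate((ix, iy, iz))
        ]
        v = self.velocity[ix, iy, iz]
        return pd.DataFrame(
            {
                "ix": ix,
                "iy": iy,
                "iz": iz,
                "x_um": centers[0],
                "y_um": centers[1],
                "z_um": centers[2],
                "vx": v[:, 0],
                "vy": v[:, 1],
                "vz": v[:, 2],
                "speed": np.linalg.norm(v, axis=1),
                "n": self.counts[ix, iy, iz],
            }
        )


def build_flow_field(
    tracks: list[BeadTrack],
    frame_rate: float,
    spacing: tuple[float, float, float] = (4.0, 4.0, 2.0),
    origin: np.ndarray | None = None,
) -> FlowField:
    """Voxel-average instantaneous track velocities into a mean flow field.

    For every consecutive position pair the velocity (displacement times
    frame rate, accounting for frame gaps) is assigned to the voxel holding
    the midpoint; per-voxel arithmetic means pool all assignments.
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    mids = []
    vels = []
    for tr in tracks:
        if len(tr) < 2:
            continue
        dt = np.diff(tr.frames) / frame_rate
        disp = np.diff(tr.positions, axis=0)
        mids.append(0.5 * (tr.positions[1:] + tr.positions[:-1]))
        vels.append(disp / dt[:, None])
    if not mids:
        raise EmptyFieldError("no velocity samples in any track")
    mids = np.concatenate(mids)
    vels = np.concatenate(vels)
    if origin is None:
        origin = np.floor(mids.min(axis=0) / spacing) * spacing
    origin = np.asarray(origin, dtype=float)
    idx = np.floor((mids - origin) / spacing).astype(int)
    inside = np.all(idx >= 0, axis=1)
    idx, vels = idx[inside], vels[inside]
    if idx.size == 0:
        raise EmptyFieldError("no velocity samples inside the grid")
    dims = idx.max(axis=0) + 1
    counts = np.zeros(dims, dtype=int)
    vsum = np.zeros((*dims, 3))
    np.add.at(counts, tuple(idx.T), 1)
    np.add.at(vsum, tuple(idx.T), vels)
    velocity = np.full((*dims, 3), np.nan)
    filled = counts > 0
    velocity[filled] = vsum[filled] / counts[filled, None]
    return FlowField(origin, spacing, velocity, counts)


def estimate_glass_z(
    tracks: list[BeadTrack],
    max_displacement_um: float,
) -> float:
    """Mean z of nonmoving beads' time-averaged positions.

    A track counts as nonmoving when its per-axis position range stays below
    ``max_displacement_um`` (the threshold is explicit configuration; a
    sensible default is a few step standard deviations of the expected
    diffusion). Raises if no track qualifies.
    """
    z_values = []
    for tr in tracks:
        span = tr.positions.max(axis=0) - tr.positions.min(axis=0)
        if np.all(span < max_displacement_um):
            z_values.append(tr.positions[:, 2].mean())
    if not z_values:
        raise EmptyFieldError("no nonmoving beads found")
    return float(np.mean(z_values))


def project_flow_2d(field: FlowField) -> tuple[np.ndarray, np.ndarray]:
    """Count-weighted z-projection of the flow field.

    Returns (velocity (nx, ny, 3) with NaN in empty columns, counts (nx, ny));
    projected speeds are the norms of the projected vectors.
    """
    if not np.any(field.counts):
        raise EmptyFieldError("empty field")
    counts2d = field.counts.sum(axis=2)
    weighted = np.nansum(
        np.where(
            field.counts[..., None] > 0, field.velocity * field.counts[..., None], 0.0
        ),
        axis=2,
    )
    velocity2d = np.full(weighted.shape, np.nan)
    filled = counts2d > 0
    velocity2d[filled] = weighted[filled] / counts2d[filled, None]
    return velocity2d, counts2d


def stokeslet_velocity(
    points: np.ndarray,
    force_location: np.ndarray,
    force: np.ndarray,
    viscosity: float = 1e-3,
) -> np.ndarray:
    """Analytic point-force (Stokeslet) flow field, for synthetic ground truth.

    u_i = F_j / (8*pi*mu) * (delta_ij / r + r_i*r_j / r**3). Units follow the
    inputs (force in N, distances in m gives m/s).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    r_vec = points - np.asarray(force_location, dtype=float)
    r = np.linalg.norm(r_vec, axis=1, keepdims=True)
    r = np.where(r > 0, r, np.inf)
    f = np.asarray(force, dtype=float)
    coeff = 1.0 / (8.0 * np.pi * viscosity)
    return coeff * (f / r + r_vec * (r_vec @ f)[:, None] / r**3)
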