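"""Shared container for one timepoint of four co-registered focal-plane images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_PLANES = 4


@dataclass
class MultifocalFrame:
    """One timepoint's four focal-plane images plus their focal offsets.

    Parameters
    ----------
    planes : ndarray, shape (4, H, W)
        Intensity images (counts), one per focal plane.
    plane_offsets : ndarray, shape (4,)
        Sample-space focal position of each plane in µm, relative to plane 1.
    pixel_pitch : float
        Sample-space pixel pitch in µm/px.
    timestamp : float
        Acquisition time in seconds.
    """

    planes: np.ndarray
    plane_offsets: np.ndarray
    pixel_pitch: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        self.plane_offsets = np.asarray(self.plane_offsets, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] != N_PLANES:
            raise ValueError(
                f"planes must have shape (4, H, W), got {self.planes.shape}"
            )
        if self.plane_offsets.shape != (N_PLANES,):
            raise ValueError("plane_offsets must have length 4")
        if not np.all(np.isfinite(self.plane_offsets)):
            raise ValueError("plane_offsets must be finite")
        if len(np.unique(self.plane_offsets)) != N_PLANES:
            raise ValueError("plane_offsets must be distinct")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def copy(self) -> "MultifocalFrame":
        return MultifocalFrame(
            self.planes.copy(),
            self.plane_offsets.copy(),
            self.pixel_pitch,
            self.timestamp,
        )

    def to_tiled(self) -> np.ndarray:
        """Pack the four planes into one 2x2 quadrant-tiled image.

        Quadrant order: plane 1 top-left, plane 2 top-right, plane 3
        bottom-left, plane 4 bottom-right.
        """
        h, w = self.shape
        tiled = np.zeros((2 * h, 2 * w), dtype=self.planes.dtype)
        tiled[:h, :w] = self.planes[0]
        tiled[:h, w:] = self.planes[1]
        tiled[h:, :w] = self.planes[2]
        tiled[h:, w:] = self.planes[3]
        return tiled

    @classmethod
    def from_tiled(
        cls,
        tiled: np.ndarray,
        plane_offsets: np.ndarray,
        pixel_pitch: float,
        timestamp: float = 0.0,
    ) -> "MultifocalFrame":
        tiled = np.asarray(tiled)
        if tiled.shape[0] % 2 or tiled.shape[1] % 2:
            raise ValueError("tiled image must have even dimensions")
        h, w = tiled.shape[0] // 2, tiled.shape[1] // 2
        planes = np.stack(
            [tiled[:h, :w], tiled[:h, w:], tiled[h:, :w], tiled[h:, w:]]
        )
        return cls(planes, plane_offsets, pixel_pitch, timestamp)
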