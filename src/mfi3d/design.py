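"""Closed-form design identities for multifocal imaging experiments.

Small helpers used when sizing an experiment: sampled-volume comparisons
between methods, Nyquist acquisition rates for beat harmonics, the expected
near-flagellum flow speed scale, and rolling-rate unit conversion.
"""

from __future__ import annotations

import math


def sampled_volume(dims_um: tuple[float, float, float]) -> float:
    """Volume of a rectangular sampled region (µm³)."""
    x, y, z = dims_um
    if min(x, y, z) <= 0:
        raise ValueError("dimensions must be positive")
    return x * y * z


def volume_ratio(
    dims_um: tuple[float, float, float], other_dims_um: tuple[float, float, float]
) -> float:
    """Fold difference between two sampled volumes."""
    return sampled_volume(dims_um) / sampled_volume(other_dims_um)


def nyquist_rate(f_max_hz: float) -> float:
    """Minimum acquisition rate (fps) resolving a component at f_max (Hz)."""
    if f_max_hz <= 0:
        raise ValueError("frequency must be positive")
    return 2.0 * f_max_hz


def harmonic_frequency(f0_hz: float, harmonic: int = 2) -> float:
    """Frequency of the n-th harmonic of a fundamental beat frequency."""
    return harmonic * f0_hz


def near_flagellum_flow_speed(
    flagellum_length_um: float, beat_frequency_hz: float
) -> float:
    """Flow-speed scale 0.1 * L / T near a beating flagellum (µm/s)."""
    return 0.1 * flagellum_length_um * beat_frequency_hz


def rolling_rate_rad_per_s(rolling_frequency_hz: float) -> float:
    """Convert a rolling frequency (Hz) to an angular rate (rad/s)."""
    return 2.0 * math.pi * rolling_frequency_hz
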