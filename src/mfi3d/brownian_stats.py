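"""Localization precision estimated from tracked Brownian motion.

The measured displacement distribution of a diffusing bead is the convolution
of the diffusion kernel with the (assumed Gaussian) localization-error
distribution, so the variances add: sigma_M**2 = sigma_P**2 + sigma_D**2 with
sigma_D**2 = 2*D*dt and D from the Stokes-Einstein relation. Inverting this
gives the per-axis precision sigma_P = sqrt(sigma_M**2 - 2*D*dt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from mfi3d.bead3d import BeadTrack
from mfi3d.optics_forward import DiffusionModel

AXES = {"x": 0, "y": 1, "z": 2}


class InsufficientDataError(RuntimeError):
    pass


@dataclass
class DisplacementDistribution:
    """Pooled displacement samples at a fixed lag, with fitted variance."""

    axis: str
    samples: np.ndarray  # µm
    lag_time: float  # s
    sigma_m_sq: float  # µm², zero-mean Gaussian MLE = mean of squares
    n: int


@dataclass
class PrecisionEstimate:
    axis: str
    sigma_m: float  # µm
    sigma_d: float  # µm
    sigma_p: float  # µm
    diffusion_coefficient: float  # m² s⁻¹
    lag_time: float  # s
    n: int
    nonphysical: bool = False  # sigma_M² < sigma_D²: sigma_P reported as 0


def fit_displacement_distribution(
    tracks: list[BeadTrack],
    axis: str,
    lag_time: float,
    lag_frames: int = 1,
    min_samples: int = 50,
    subtract_drift: bool = False,
) -> DisplacementDistribution:
    """Pool per-track displacements at the given lag and fit their variance.

    The variance is the maximum-likelihood estimate for a zero-mean Gaussian
    (mean of squared displacements) — no histogram binning. With
    ``subtract_drift`` each track's mean displacement is removed first, which
    makes the estimate invariant to constant drift.
    """
    ai = AXES[axis]
    pooled = []
    for tr in tracks:
        coords = tr.positions[:, ai]
        if len(coords) <= lag_frames:
            continue
        d = coords[lag_frames:] - coords[:-lag_frames]
        if subtract_drift:
            d = d - d.mean()
        pooled.append(d)
    samples = np.concatenate(pooled) if pooled else np.empty(0)
    if samples.size < min_samples:
        raise InsufficientDataError(
            f"{samples.size} displacement samples < required {min_samples}"
        )
    sigma_m_sq = float(np.mean(samples**2))
    return DisplacementDistribution(
        axis, samples, lag_time * lag_frames, sigma_m_sq, samples.size
    )


def fit_displacement_histogram(
    dist: DisplacementDistribution, n_bins: int = 51
) -> float:
    """Cross-check path: fit the diffusion PDF to the normalized histogram.

    Fits a zero-mean Gaussian density to the binned displacement histogram by
    least squares and returns the fitted variance (µm²).
    """
    from scipy.optimize import curve_fit

    counts, edges = np.histogram(dist.samples, bins=n_bins, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])

    def pdf(d, var):
        return np.exp(-(d**2) / (2.0 * var)) / np.sqrt(2.0 * math.pi * var)

    popt, _ = curve_fit(pdf, centers, counts, p0=[max(dist.sigma_m_sq, 1e-8)])
    return float(popt[0])


def estimate_precision(
    dist: DisplacementDistribution, model: DiffusionModel
) -> PrecisionEstimate:
    """Deconvolve the diffusion kernel: sigma_P = sqrt(sigma_M² - 2*D*dt).

    If the measured variance undershoots the diffusion variance (possible at
    finite sample size), the result is flagged nonphysical and sigma_P is
    reported as zero rather than NaN.
    """
    if dist.lag_time <= 0:
        raise ValueError("lag time must be positive")
    d_um2 = model.d_um2_per_s
    sigma_d_sq = 2.0 * d_um2 * dist.lag_time
    diff = dist.sigma_m_sq - sigma_d_sq
    nonphysical = diff < 0
    sigma_p = 0.0 if nonphysical else math.sqrt(diff)
    return PrecisionEstimate(
        axis=dist.axis,
        sigma_m=math.sqrt(dist.sigma_m_sq),
        sigma_d=math.sqrt(sigma_d_sq),
        sigma_p=sigma_p,
        diffusion_coefficient=model.d_m2_per_s,
        lag_time=dist.lag_time,
        n=dist.n,
        nonphysical=nonphysical,
    )


def precision_report(
    tracks: list[BeadTrack],
    model: DiffusionModel,
    lag_frames: int = 1,
    subtract_drift: bool = False,
) -> dict:
    """Per-axis pooled precision estimates as a JSON-ready dict."""
    report = {}
    for axis in AXES:
        dist = fit_displacement_distribution(
            tracks,
            axis,
            model.frame_period,
            lag_frames,
            subtract_drift=subtract_drift,
        )
        est = estimate_precision(dist, model)
        report[axis] = {
            "sigma_M_um": est.sigma_m,
            "sigma_D_um": est.sigma_d,
            "sigma_P_um": est.sigma_p,
            "n": est.n,
            "nonphysical": est.nonphysical,
        }
    return report


def per_bead_precision(
    tracks: list[BeadTrack],
    model: DiffusionModel,
    axis: str,
    lag_frames: int = 1,
    min_samples: int = 10,
) -> np.ndarray:
    """Per-track sigma_P values (µm); the mean of these is the per-bead
    pathway, as opposed to pooling all displacements first."""
    out = []
    for tr in tracks:
        try:
            dist = fit_displacement_distribution(
                [tr], axis, model.frame_period, lag_frames, min_samples
            )
        except InsufficientDataError:
            continue
        out.append(estimate_precision(dist, model).sigma_p)
    return np.asarray(out)
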