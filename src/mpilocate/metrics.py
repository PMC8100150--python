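"""Localization-quality metrics and reconstruction post-processing.

Two scalar metrics compare a reconstructed distribution D_inv with the
true one D_ori, both max-normalized (source amplitudes carry no absolute
scale):

    average deviation = sum_k |D_inv,k - D_ori,k| / N      (N masked voxels)
    location error    = || argmax(D_ori) - argmax(D_inv) ||_2   (cm)

Thresholding and local-maxima detection serve reporting (multi-source
distinguishability); metrics are always computed on unthresholded volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import SourceDistribution

__all__ = [
    "MetricsReport",
    "average_deviation",
    "location_error",
    "argmax_location",
    "threshold_distribution",
    "find_local_maxima",
    "evaluate",
]


@dataclass(frozen=True)
class MetricsReport:
    """Conformity of a reconstruction with the true source."""

    location_error: float          # cm
    average_deviation: float       # dimensionless, on max-1 scale
    argmax_original: np.ndarray    # cm
    argmax_inverse: np.ndarray     # cm
    n_voxels: int

    def as_dict(self) -> dict:
        return {
            "max_x": float(self.argmax_inverse[0]),
            "max_y": float(self.argmax_inverse[1]),
            "max_z": float(self.argmax_inverse[2]),
            "location_error": self.location_error,
            "average_deviation": self.average_deviation,
        }


def _amplitudes(d) -> np.ndarray:
    return np.asarray(getattr(d, "amplitude", d), dtype=float).ravel()


def average_deviation(d_inv, d_ori, normalize: bool = True) -> float:
    """Mean absolute voxelwise difference over the masked voxels.

    With ``normalize`` (the default) both distributions are first rescaled
    to maximum 1, making the value comparable across configurations.
    """
    a = _amplitudes(d_inv)
    b = _amplitudes(d_ori)
    if a.shape != b.shape:
        raise ValueError("distributions are defined on different grids")
    if normalize:
        if a.max() > 0:
            a = a / a.max()
        if b.max() > 0:
            b = b / b.max()
    return float(np.abs(a - b).mean())


def location_error(loc_orig, loc_inv) -> float:
    """Euclidean distance between true and reconstructed maxima, cm."""
    return float(np.linalg.norm(np.asarray(loc_orig, dtype=float)
                                - np.asarray(loc_inv, dtype=float)))


def argmax_location(d: SourceDistribution) -> np.ndarray:
    """Position (cm) of the maximum amplitude.

    Ties break to the lowest linear index (x fastest, then y, then z).
    """
    amp = d.amplitude
    if amp.size == 0 or amp.max() <= 0:
        raise ValueError("distribution has no positive voxel")
    return d.grid.masked_positions[int(np.argmax(amp))].copy()


def threshold_distribution(d: SourceDistribution,
                           t: float) -> SourceDistribution:
    """Zero voxels below ``t`` times the maximum (reporting filter only)."""
    if not 0 <= t < 1:
        raise ValueError("threshold must lie in [0, 1)")
    amp = d.amplitude
    out = np.where(amp >= t * amp.max(), amp, 0.0)
    return SourceDistribution(d.grid, out)


def find_local_maxima(d: SourceDistribution, t: float = 0.0) -> np.ndarray:
    """Positions (cm) of 26-connected local maxima at least ``t``*max.

    A voxel qualifies when its amplitude is >= every in-mask 26-neighbour
    and >= t * max. Plateaus (connected runs of equal qualifying values)
    coalesce to their lexicographically first voxel. Returns an (m, 3)
    array sorted by linear index.
    """
    if not 0 <= t < 1:
        raise ValueError("threshold must lie in [0, 1)")
    amp = d.amplitude
    if amp.size == 0 or amp.max() <= 0:
        return np.empty((0, 3))
    vol = d.grid.embed(amp, fill=-np.inf)
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = ndimage.maximum_filter(
        vol, footprint=footprint, mode="constant", cval=-np.inf)
    candidate = (vol == local_max) & np.isfinite(vol) & (vol >= t * amp.max())
    labels, n_lab = ndimage.label(candidate, structure=footprint)
    positions = []
    nx, ny, _ = d.grid.shape
    for lab in range(1, n_lab + 1):
        ix, iy, iz = np.nonzero(labels == lab)
        linear = ix + nx * (iy + ny * iz)
        first = np.argmin(linear)
        ijk = np.array([ix[first], iy[first], iz[first]])
        positions.append(d.grid.origin + ijk * d.grid.spacing)
    positions.sort(key=lambda p: tuple(reversed(p)))  # by z, then y, then x
    return np.asarray(positions).reshape(-1, 3)


def evaluate(original: SourceDistribution,
             inverse: SourceDistribution) -> MetricsReport:
    """Full metric report for a reconstruction against the true source."""
    loc_o = argmax_location(original)
    loc_i = argmax_location(inverse)
    return MetricsReport(
        location_error=location_error(loc_o, loc_i),
        average_deviation=average_deviation(inverse, original),
        argmax_original=loc_o,
        argmax_inverse=loc_i,
        n_voxels=original.grid.n_masked,
    )
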