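"""Voxelized calculation volumes, planar sensor arrays, and synthetic sources.

The calculation space (the "BEM" in biomagnetic usage: the homogeneous
volume in which magnetic-nanoparticle sources may lie) is a regular grid of
voxel nodes. Nodes include both boundaries of each axis, so an extent of
6.0 cm at 0.1 cm spacing yields 61 nodes per axis and printed coordinates
such as [1.5, 1.8, 1.0] or [5.0, 5.0, 4.0] fall exactly on nodes.

Linear voxel ordering is fixed: x fastest, then y, then z. All coordinates
are physical centimetres with the origin at the volume's minimum corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "SensorArray",
    "SourceDistribution",
    "make_cuboid_bem",
    "make_brain_stand_in",
    "make_sensor_plane",
    "gaussian_source",
    "multi_gaussian_source",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid with an optional inclusion mask.

    Parameters
    ----------
    origin : (3,) array
        Minimum-corner node position, cm.
    spacing : float
        Node spacing, cm (isotropic).
    shape : (3,) int tuple
        Node counts (nx, ny, nz).
    mask : (n,) bool array
        Flat inclusion mask in linear order (x fastest, then y, then z).
        ``True`` marks a voxel inside the calculation space.
    """

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(s < 1 for s in self.shape):
            raise ValueError("shape entries must be positive")
        mask = np.asarray(self.mask, dtype=bool).ravel()
        if mask.size != self.n_total:
            raise ValueError(
                f"mask has {mask.size} entries, expected {self.n_total}"
            )
        object.__setattr__(self, "mask", mask)

    # -- indexing ---------------------------------------------------------

    @property
    def n_total(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def n_masked(self) -> int:
        """Number of voxels inside the calculation space (N in the metrics)."""
        return int(self.mask.sum())

    def unravel(self, k: np.ndarray | int) -> np.ndarray:
        """Linear index -> (ix, iy, iz), x fastest."""
        k = np.asarray(k)
        nx, ny, _ = self.shape
        return np.stack([k % nx, (k // nx) % ny, k // (nx * ny)], axis=-1)

    def ravel(self, ijk: np.ndarray) -> np.ndarray:
        """(ix, iy, iz) -> linear index, inverse of :meth:`unravel`."""
        ijk = np.asarray(ijk)
        nx, ny, _ = self.shape
        return ijk[..., 0] + nx * (ijk[..., 1] + ny * ijk[..., 2])

    @property
    def positions(self) -> np.ndarray:
        """(n_total, 3) node positions in linear order, cm."""
        ijk = self.unravel(np.arange(self.n_total))
        return self.origin + ijk * self.spacing

    @property
    def masked_positions(self) -> np.ndarray:
        """(n_masked, 3) positions of in-mask voxels, cm."""
        return self.positions[self.mask]

    @property
    def extent(self) -> np.ndarray:
        """Physical size along each axis (distance between boundary nodes), cm."""
        return (np.asarray(self.shape) - 1) * self.spacing

    @property
    def top_z(self) -> float:
        """z of the highest node, cm."""
        return float(self.origin[2] + (self.shape[2] - 1) * self.spacing)

    def embed(self, amplitude: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-masked-voxel values into a full (nx, ny, nz) array."""
        amplitude = np.asarray(amplitude, dtype=float)
        if amplitude.shape != (self.n_masked,):
            raise ValueError("amplitude length must equal the masked voxel count")
        flat = np.full(self.n_total, fill, dtype=float)
        flat[self.mask] = amplitude
        nx, ny, nz = self.shape
        # linear order is x fastest -> Fortran raveling of an (nx,ny,nz) array
        return flat.reshape((nx, ny, nz), order="F")


@dataclass(frozen=True)
class SensorArray:
    """Planar scanning positions sharing one sensing direction.

    positions : (m, 3) array, cm; all share z = plane_z.
    direction : unit 3-vector, the measured field component.
    """

    positions: np.ndarray
    direction: np.ndarray
    plane_z: float

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(direction)
        if not np.isclose(norm, 1.0):
            if norm == 0:
                raise ValueError("direction must be a nonzero vector")
            direction = direction / norm
        if not np.allclose(pos[:, 2], self.plane_z):
            raise ValueError("all sensor positions must lie at z = plane_z")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "direction", direction)
        object.__setattr__(self, "plane_z", float(self.plane_z))

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SourceDistribution:
    """Nonnegative source amplitude per masked voxel of a grid."""

    grid: VoxelGrid
    amplitude: np.ndarray

    def __post_init__(self):
        amp = np.asarray(self.amplitude, dtype=float).ravel()
        if amp.shape != (self.grid.n_masked,):
            raise ValueError(
                "amplitude length must equal the grid's masked voxel count"
            )
        if np.any(amp < 0):
            raise ValueError("source amplitudes must be nonnegative")
        object.__setattr__(self, "amplitude", amp)

    def normalized(self) -> "SourceDistribution":
        """Rescale so the maximum amplitude is 1 (identity on all-zero)."""
        m = self.amplitude.max() if self.amplitude.size else 0.0
        if m <= 0:
            return self
        return SourceDistribution(self.grid, self.amplitude / m)

    def volume(self, fill: float = 0.0) -> np.ndarray:
        """Amplitudes as a dense (nx, ny, nz) array."""
        return self.grid.embed(self.amplitude, fill=fill)


# -- constructors ---------------------------------------------------------


def make_cuboid_bem(extent, spacing: float) -> VoxelGrid:
    """Cuboid calculation volume with all voxels inside.

    ``extent`` is the physical edge length per axis (cm) and must be a
    multiple of ``spacing``; nodes include both boundaries, so the node
    count per axis is ``extent/spacing + 1``.
    """
    extent = np.asarray(extent, dtype=float)
    if extent.shape != (3,) or np.any(extent <= 0):
        raise ValueError("extent must be three positive lengths")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    steps = extent / spacing
    if not np.allclose(steps, np.round(steps), atol=1e-9):
        raise ValueError(
            f"extent {extent.tolist()} cm is not a multiple of the "
            f"{spacing} cm spacing; choose a divisible extent"
        )
    shape = tuple(int(round(s)) + 1 for s in steps)
    n = shape[0] * shape[1] * shape[2]
    return VoxelGrid(
        origin=np.zeros(3), spacing=float(spacing), shape=shape,
        mask=np.ones(n, dtype=bool),
    )


def make_brain_stand_in(bbox=(5.0, 4.0, 1.5), spacing: float = 0.1) -> VoxelGrid:
    """Ellipsoidal stand-in for an anatomical (e.g. mouse-brain) volume.

    The mask is the ellipsoid inscribed in ``bbox`` (semi-axes bbox/2,
    centred). This is a synthetic geometric stand-in, not an anatomical
    segmentation; results on it probe trends, not absolute values.
    """
    bbox = np.asarray(bbox, dtype=float)
    if bbox.shape != (3,) or np.any(bbox <= 0):
        raise ValueError("bbox must be three positive lengths")
    if spacing > bbox.min() / 2:
        raise ValueError(
            f"spacing {spacing} cm exceeds half the smallest bbox edge; "
            "the ellipsoid mask would be empty"
        )
    grid = make_cuboid_bem(_snap_extent(bbox, spacing), spacing)
    center = grid.extent / 2
    semi = bbox / 2
    rel = (grid.positions - center) / semi
    mask = np.einsum("ij,ij->i", rel, rel) <= 1.0
    return VoxelGrid(origin=grid.origin, spacing=grid.spacing,
                     shape=grid.shape, mask=mask)


def _snap_extent(bbox: np.ndarray, spacing: float) -> np.ndarray:
    """Round a bounding box up to the nearest node-aligned extent."""
    steps = np.ceil(np.round(bbox / spacing, 9))
    return steps * spacing


def make_sensor_plane(xy_extent, interval: float, plane_z: float,
                      direction=(0.0, 0.0, 1.0), center_xy=None) -> SensorArray:
    """Regular XY grid of sensors at height ``plane_z``.

    ``xy_extent`` (cm) must be a multiple of ``interval``; the grid has
    ``extent/interval + 1`` sensors per axis. ``center_xy`` places the
    plane's centre (defaults to xy_extent/2, i.e. the plane spans
    [0, extent] per axis); pass the volume's footprint centre to make the
    plane concentric with it.
    """
    xy_extent = np.asarray(xy_extent, dtype=float)
    if xy_extent.shape != (2,) or np.any(xy_extent <= 0):
        raise ValueError("xy_extent must be two positive lengths")
    if interval <= 0:
        raise ValueError("interval must be positive")
    steps = xy_extent / interval
    if not np.allclose(steps, np.round(steps), atol=1e-9):
        raise ValueError("xy_extent must be a multiple of interval")
    nx, ny = (int(round(s)) + 1 for s in steps)
    if center_xy is None:
        center_xy = xy_extent / 2
    center_xy = np.asarray(center_xy, dtype=float)
    x0 = center_xy[0] - xy_extent[0] / 2
    y0 = center_xy[1] - xy_extent[1] / 2
    xs = x0 + np.arange(nx) * interval
    ys = y0 + np.arange(ny) * interval
    # x fastest, then y
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    positions = np.column_stack(
        [gx.ravel(order="C"), gy.ravel(order="C"),
         np.full(nx * ny, float(plane_z))]
    )
    return SensorArray(positions=positions, direction=direction,
                       plane_z=float(plane_z))


def _check_center_inside(grid: VoxelGrid, center: np.ndarray) -> None:
    lo = grid.origin - 1e-9
    hi = grid.origin + grid.extent + 1e-9
    if np.any(center < lo) or np.any(center > hi):
        raise ValueError(
            f"source center {center.tolist()} cm lies outside the grid "
            f"bounds {grid.origin.tolist()}..{(grid.origin + grid.extent).tolist()}"
        )


def gaussian_source(grid: VoxelGrid, center, sigma: float) -> SourceDistribution:
    """Isotropic Gaussian particle concentration, normalized to max 1.

    amplitude(r) = exp(-||r - center||^2 / (2 sigma^2)) on masked voxels.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    center = np.asarray(center, dtype=float)
    _check_center_inside(grid, center)
    d2 = np.sum((grid.masked_positions - center) ** 2, axis=1)
    amp = np.exp(-d2 / (2.0 * sigma ** 2))
    return SourceDistribution(grid, amp).normalized()


def multi_gaussian_source(grid: VoxelGrid, centers, sigma: float) -> SourceDistribution:
    """Sum of per-center Gaussians, renormalized to max 1."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        raise ValueError("at least one center is required")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    total = np.zeros(grid.n_masked)
    for c in centers:
        _check_center_inside(grid, c)
        d2 = np.sum((grid.masked_positions - c) ** 2, axis=1)
        total += np.exp(-d2 / (2.0 * sigma ** 2))
    return SourceDistribution(grid, total).normalized()
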