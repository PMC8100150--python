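"""Dipole lead fields under a z-directed excitation field.

Each in-mask voxel holds magnetic nanoparticles whose moment responds
linearly to the local applied field B(z) = g*z + b (constant susceptibility;
the Langevin law is linear with slope 1/3 at small fields, and that slope is
folded into a single coupling constant ``kappa``). The induced field at a
sensor is the point-dipole field projected on the sensor direction:

    A[j, k] = (mu0 / 4 pi) * (3 (m_k . d^) d^ - m_k) / ||d||^3 . n_S,
    d = r_S,j - r_P,k

Interfaces use cm and mT; geometry is converted to metres internally, and
matrix entries are tesla per unit source amplitude. Every reported metric is
invariant to the overall scale of the matrix, so kappa defaults to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import SensorArray, SourceDistribution, VoxelGrid

__all__ = [
    "AppliedFieldZ",
    "LeadField",
    "FieldMap",
    "applied_field_at",
    "moment_at",
    "lead_field_entry",
    "build_lead_field",
    "field_map",
    "stack_lead_fields",
    "stack_field_maps",
    "MU0_OVER_4PI",
]

MU0_OVER_4PI = 1.0e-7  # T m / A
CM = 1.0e-2  # m per cm
MT = 1.0e-3  # T per mT

#: warn when a dense lead field would exceed this many entries
ENTRY_BUDGET = 2 ** 28


@dataclass(frozen=True)
class AppliedFieldZ:
    """z-directed excitation field B(z) = gradient * z + bias.

    gradient : mT/cm (may be negative; depth encoding relies on the sign
    change of the field inside the volume). bias : mT.
    """

    gradient: float = 0.0
    bias: float = 0.5

    def __post_init__(self):
        if not (np.isfinite(self.gradient) and np.isfinite(self.bias)):
            raise ValueError("gradient and bias must be finite")


def applied_field_at(field: AppliedFieldZ, z) -> np.ndarray | float:
    """Applied field g*z + b at height z (cm), in mT."""
    return field.gradient * np.asarray(z, dtype=float) + field.bias


def moment_at(field: AppliedFieldZ, z, kappa: float = 1.0) -> np.ndarray:
    """Induced dipole moment (A m^2) of a unit-amplitude voxel at height z.

    m = kappa * B(z) * z_hat with B in tesla: linear response with a
    z-directed moment following the z-directed excitation.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    b = np.atleast_1d(applied_field_at(field, z)) * MT
    m = np.zeros(b.shape + (3,))
    m[..., 2] = kappa * b
    return m if m.shape[0] > 1 else m[0]


def lead_field_entry(m, r_p, r_s, n_s) -> float:
    """Sensor-direction component (tesla) of the dipole field of moment m.

    Positions in cm; m in A m^2; n_s a unit vector.
    """
    m = np.asarray(m, dtype=float)
    d = (np.asarray(r_s, dtype=float) - np.asarray(r_p, dtype=float)) * CM
    r = np.linalg.norm(d)
    if r == 0:
        raise ValueError("sensor position coincides with the voxel position")
    n_s = np.asarray(n_s, dtype=float)
    dhat = d / r
    b = MU0_OVER_4PI * (3.0 * np.dot(m, dhat) * dhat - m) / r ** 3
    return float(np.dot(b, n_s))


@dataclass(frozen=True)
class LeadField:
    """Stacked dipole lead-field matrix.

    matrix : (rows, n_masked) array, tesla per unit amplitude. Rows are
    grouped in blocks, one block per (sensor array, applied field) pair;
    ``block_offsets[i]`` is the first row of block i.
    """

    matrix: np.ndarray
    grid: VoxelGrid
    sensors: tuple[SensorArray, ...]
    fields: tuple[AppliedFieldZ, ...]
    block_offsets: tuple[int, ...]
    kappa: float = 1.0

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != self.grid.n_masked:
            raise ValueError("matrix columns must match the masked voxel count")
        if len(self.sensors) != len(self.fields):
            raise ValueError("one applied field per sensor block is required")
        rows = sum(s.n_sensors for s in self.sensors)
        if mat.shape[0] != rows:
            raise ValueError("matrix rows must equal the total sensor count")
        if not np.all(np.isfinite(mat)):
            raise ValueError("lead field contains non-finite entries")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "sensors", tuple(self.sensors))
        object.__setattr__(self, "fields", tuple(self.fields))
        object.__setattr__(self, "block_offsets", tuple(self.block_offsets))

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_blocks(self) -> int:
        return len(self.sensors)

    def block(self, i: int) -> np.ndarray:
        """Row slice of block i."""
        start = self.block_offsets[i]
        stop = (self.block_offsets[i + 1] if i + 1 < self.n_blocks
                else self.n_rows)
        return self.matrix[start:stop]


@dataclass(frozen=True)
class FieldMap:
    """Sensor readings (tesla), block structure mirroring a LeadField."""

    values: np.ndarray
    sensors: tuple[SensorArray, ...]
    block_offsets: tuple[int, ...]

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float).ravel()
        rows = sum(s.n_sensors for s in self.sensors)
        if vals.size != rows:
            raise ValueError("field-map length must equal the sensor count")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sensors", tuple(self.sensors))
        object.__setattr__(self, "block_offsets", tuple(self.block_offsets))


def build_lead_field(grid: VoxelGrid, sensors: SensorArray,
                     field: AppliedFieldZ, kappa: float = 1.0) -> LeadField:
    """Dense single-block lead field A[j, k] for one sensor plane and field.

    Vectorized evaluation of the dipole expression over all sensor/voxel
    pairs; raises if any sensor coincides with a voxel.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if grid.n_masked == 0:
        raise ValueError("grid mask is empty")
    n_entries = sensors.n_sensors * grid.n_masked
    if n_entries > ENTRY_BUDGET:
        warnings.warn(
            f"dense lead field with {n_entries:.2e} entries exceeds the "
            f"{ENTRY_BUDGET:.2e}-entry budget; consider a coarser grid",
            ResourceWarning, stacklevel=2,
        )
    r_p = grid.masked_positions * CM            # (n, 3)
    r_s = sensors.positions * CM                # (m, 3)
    n_s = sensors.direction
    # z-directed moment magnitude per voxel (A m^2 per unit amplitude)
    m_z = kappa * MT * np.asarray(
        applied_field_at(field, grid.masked_positions[:, 2]))
    d = r_s[:, None, :] - r_p[None, :, :]       # (m, n, 3)
    r2 = np.einsum("mnk,mnk->mn", d, d)
    if np.any(r2 == 0):
        raise ValueError("a sensor position coincides with a voxel position")
    inv_r = 1.0 / np.sqrt(r2)
    inv_r3 = inv_r ** 3
    # B.n = mu0/4pi * m_z * (3 d_z (d.n) / r^5 - n_z / r^3)
    d_dot_n = np.einsum("mnk,k->mn", d, n_s)
    a = MU0_OVER_4PI * (
        3.0 * d[..., 2] * d_dot_n * inv_r3 * inv_r ** 2 - n_s[2] * inv_r3
    )
    a *= m_z[None, :]
    return LeadField(matrix=a, grid=grid, sensors=(sensors,),
                     fields=(field,), block_offsets=(0,), kappa=kappa)


def field_map(lf: LeadField, u: SourceDistribution) -> FieldMap:
    """Noise-free forward map f = A u."""
    if u.grid is not lf.grid and not _same_grid(u.grid, lf.grid):
        raise ValueError("source grid does not match the lead field grid")
    return FieldMap(values=lf.matrix @ u.amplitude, sensors=lf.sensors,
                    block_offsets=lf.block_offsets)


def noisy_field_map(lf: LeadField, u: SourceDistribution, sigma: float,
                    rng: np.random.Generator) -> FieldMap:
    """Forward map with additive Gaussian sensor noise (optional hook).

    The default pipeline is noise-free; this exists for exploratory use.
    """
    clean = field_map(lf, u)
    return FieldMap(values=clean.values + rng.normal(0.0, sigma,
                                                     clean.values.size),
                    sensors=clean.sensors, block_offsets=clean.block_offsets)


def _same_grid(a: VoxelGrid, b: VoxelGrid) -> bool:
    return (a.shape == b.shape and np.allclose(a.origin, b.origin)
            and np.isclose(a.spacing, b.spacing)
            and np.array_equal(a.mask, b.mask))


def stack_lead_fields(blocks) -> LeadField:
    """Row-wise concatenation of lead fields sharing one grid."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("at least one lead field is required")
    grid = blocks[0].grid
    for b in blocks[1:]:
        if not _same_grid(grid, b.grid):
            raise ValueError("all lead fields must share the same grid")
    sensors = tuple(s for b in blocks for s in b.sensors)
    fields = tuple(f for b in blocks for f in b.fields)
    offsets, row = [], 0
    for s in sensors:
        offsets.append(row)
        row += s.n_sensors
    return LeadField(matrix=np.vstack([b.matrix for b in blocks]), grid=grid,
                     sensors=sensors, fields=fields,
                     block_offsets=tuple(offsets), kappa=blocks[0].kappa)


def stack_field_maps(blocks) -> FieldMap:
    """Row-wise concatenation of field maps, mirroring stack_lead_fields."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("at least one field map is required")
    sensors = tuple(s for b in blocks for s in b.sensors)
    offsets, row = [], 0
    for s in sensors:
        offsets.append(row)
        row += s.n_sensors
    return FieldMap(values=np.concatenate([b.values for b in blocks]),
                    sensors=sensors, block_offsets=tuple(offsets))
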