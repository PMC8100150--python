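"""Depth encoding with gradient excitation fields ("multiple Z scan").

Under a constant excitation field, the lead field of a planar sensor array
decays monotonically with source depth, so deep sources are poorly
localized. Applying a z-gradient g on top of the bias b makes the on-axis
response of a voxel at height z proportional to

    R(z) = (g z + b) / (z_s - z)^3,        z_s = sensor-plane height,

whose interior stationary point can be steered to any chosen layer:
dR/dz = 0 at z = z_t gives the closed form g = -3 b / (z_s + 2 z_t).
Stacking lead fields built with one such gradient per layer — the multiple
Z scan — weights every depth layer preferentially in one combined system.
The constant-field "multiple scan" (several sensor-plane heights, g = 0) is
the comparison method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import (AppliedFieldZ, LeadField, build_lead_field,
                      stack_lead_fields)
from .geometry import SensorArray, VoxelGrid, make_sensor_plane

__all__ = [
    "LayerPlan",
    "layer_z_positions",
    "solve_layer_gradient",
    "build_layer_plan",
    "on_axis_response",
    "multiple_z_scan_lead_field",
    "multiple_plane_scan",
]


@dataclass(frozen=True)
class LayerPlan:
    """Per-layer gradients steering the lead-field extremum depth.

    layer_z : layer heights in cm, strictly decreasing, ending at 0 (volume
    bottom). gradients : mT/cm, one per layer. bias : shared bias, mT.
    """

    layer_z: tuple[float, ...]
    gradients: tuple[float, ...]
    bias: float

    def __post_init__(self):
        z = tuple(float(v) for v in self.layer_z)
        g = tuple(float(v) for v in self.gradients)
        if len(z) != len(g) or not z:
            raise ValueError("layer_z and gradients must be equal, nonempty")
        if any(b >= a for a, b in zip(z, z[1:])):
            raise ValueError("layer_z must be strictly decreasing")
        object.__setattr__(self, "layer_z", z)
        object.__setattr__(self, "gradients", g)
        object.__setattr__(self, "bias", float(self.bias))

    @property
    def n_layers(self) -> int:
        return len(self.layer_z)

    def applied_fields(self) -> list[AppliedFieldZ]:
        return [AppliedFieldZ(gradient=g, bias=self.bias)
                for g in self.gradients]

    def to_dict(self) -> dict:
        return {"n_layers": self.n_layers, "bias_mT": self.bias,
                "layers": [{"layer": i + 1, "z_cm": z, "gradient_mT_per_cm": g}
                           for i, (z, g) in enumerate(
                               zip(self.layer_z, self.gradients))]}


def layer_z_positions(n_layers: int, bem_height: float) -> np.ndarray:
    """Evenly spaced layer heights from the volume top down to z = 0.

    z_L = (n_layers - L) * bem_height / (n_layers - 1), L = 1..n_layers.
    """
    if n_layers < 2:
        raise ValueError("at least two layers are required")
    if bem_height <= 0:
        raise ValueError("bem_height must be positive")
    levels = np.arange(1, n_layers + 1)
    return (n_layers - levels) * bem_height / (n_layers - 1)


def solve_layer_gradient(bias: float, sensor_z: float,
                         target_z: float) -> float:
    """Gradient placing the on-axis response extremum at ``target_z``.

    Setting d/dz [(g z + b)/(z_s - z)^3] = 0 at z = target_z yields
    g = -3 b / (z_s + 2 target_z). Requires a nonzero bias (with b = 0 the
    response has no interior stationary point) and a sensor plane above the
    target layer.
    """
    if bias == 0:
        raise ValueError("bias must be nonzero: a pure gradient field has "
                         "no interior on-axis extremum to steer")
    if not sensor_z > target_z >= 0:
        raise ValueError("need sensor_z > target_z >= 0")
    return -3.0 * bias / (sensor_z + 2.0 * target_z)


def build_layer_plan(n_layers: int, bem_height: float, sensor_z: float,
                     bias: float = 0.5) -> LayerPlan:
    """LayerPlan with evenly spaced layers and their steering gradients."""
    zs = layer_z_positions(n_layers, bem_height)
    grads = [solve_layer_gradient(bias, sensor_z, z) for z in zs]
    return LayerPlan(layer_z=tuple(zs), gradients=tuple(grads), bias=bias)


def on_axis_response(z, field: AppliedFieldZ, sensor_z: float):
    """Signed on-axis lead-field profile (g z + b)/(z_s - z)^3 (arb. units).

    The shape in z is all that matters for extremum placement; constant
    prefactors (mu0, kappa, the factor 2 of the on-axis dipole) are dropped.
    """
    z = np.asarray(z, dtype=float)
    return (field.gradient * z + field.bias) / (sensor_z - z) ** 3


def multiple_z_scan_lead_field(grid: VoxelGrid, sensors: SensorArray,
                               plan: LayerPlan,
                               kappa: float = 1.0) -> LeadField:
    """Stacked lead field of the gradient-field multiple Z scan.

    One block per layer, each built with that layer's steering gradient and
    the shared bias, all over the same sensor plane.
    """
    if any(z >= sensors.plane_z for z in plan.layer_z):
        raise ValueError("all layers must lie below the sensor plane")
    blocks = [build_lead_field(grid, sensors, fld, kappa=kappa)
              for fld in plan.applied_fields()]
    return stack_lead_fields(blocks)


def multiple_plane_scan(grid: VoxelGrid, plane_extent, interval: float,
                        z_list, bias: float = 0.5, kappa: float = 1.0,
                        center_xy=None) -> LeadField:
    """Stacked constant-field lead field over several sensor-plane heights.

    ``z_list`` are plane heights in cm, all above the volume top; each plane
    is a regular grid of ``plane_extent``/``interval`` sensors centred on
    ``center_xy`` (defaults to the grid's footprint centre).
    """
    z_list = list(np.atleast_1d(np.asarray(z_list, dtype=float)))
    if not z_list:
        raise ValueError("z_list must contain at least one plane height")
    if any(z <= grid.top_z for z in z_list):
        raise ValueError("all sensor planes must lie above the volume top")
    if center_xy is None:
        center_xy = (grid.origin[:2] + grid.extent[:2] / 2)
    field = AppliedFieldZ(gradient=0.0, bias=bias)
    blocks = []
    for z in z_list:
        plane = make_sensor_plane(plane_extent, interval, plane_z=z,
                                  center_xy=center_xy)
        blocks.append(build_lead_field(grid, plane, field, kappa=kappa))
    return stack_lead_fields(blocks)
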