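"""Export/import of grids, sources, lead fields and field maps.

Volumes go to NIfTI (spacing in the header zooms; spatial units are cm,
recorded in the header description since NIfTI has no cm unit code) or flat
CSV. Lead fields cache to HDF5 with enough geometry metadata to rebuild the
grid and sensor blocks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forward import AppliedFieldZ, FieldMap, LeadField
from .geometry import SensorArray, SourceDistribution, VoxelGrid

__all__ = [
    "source_to_nifti", "source_to_csv", "lead_field_to_hdf5",
    "lead_field_from_hdf5", "field_map_to_csv", "residuals_to_csv",
]


def source_to_nifti(dist: SourceDistribution, path) -> None:
    """Write a source volume as NIfTI-1 (zooms = spacing; units cm)."""
    import nibabel as nib

    vol = dist.volume().astype(np.float32)
    affine = np.diag([dist.grid.spacing] * 3 + [1.0])
    affine[:3, 3] = dist.grid.origin
    img = nib.Nifti1Image(vol, affine)
    img.header["descrip"] = b"spatial units: cm"
    img.header.set_zooms((dist.grid.spacing,) * 3)
    nib.save(img, str(path))


def source_to_csv(dist: SourceDistribution, path) -> None:
    """Flat CSV: linear index, x, y, z (cm), amplitude (masked voxels)."""
    pos = dist.grid.masked_positions
    idx = np.nonzero(dist.grid.mask)[0]
    pd.DataFrame({
        "index": idx, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "amplitude": dist.amplitude,
    }).to_csv(path, index=False)


def field_map_to_csv(fm: FieldMap, path) -> None:
    """CSV of sensor x, y, z (cm), block id and reading (tesla)."""
    rows = []
    for i, s in enumerate(fm.sensors):
        start = fm.block_offsets[i]
        for j in range(s.n_sensors):
            p = s.positions[j]
            rows.append((i, p[0], p[1], p[2], fm.values[start + j]))
    pd.DataFrame(rows, columns=["block", "x", "y", "z", "value"]).to_csv(
        path, index=False)


def residuals_to_csv(residuals, path) -> None:
    pd.DataFrame({"iteration": np.arange(1, len(residuals) + 1),
                  "relative_residual": np.asarray(residuals)}).to_csv(
        path, index=False)


def lead_field_to_hdf5(lf: LeadField, path) -> None:
    """Cache a (possibly stacked) lead field with geometry metadata."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("matrix", data=lf.matrix)
        g = h5.create_group("grid")
        g.attrs["origin"] = lf.grid.origin
        g.attrs["spacing"] = lf.grid.spacing
        g.attrs["shape"] = lf.grid.shape
        g.create_dataset("mask", data=lf.grid.mask)
        h5.attrs["kappa"] = lf.kappa
        h5.attrs["block_offsets"] = lf.block_offsets
        h5.attrs["units"] = "positions cm; matrix tesla per unit amplitude"
        for i, (s, f) in enumerate(zip(lf.sensors, lf.fields)):
            b = h5.create_group(f"block{i}")
            b.create_dataset("sensor_positions", data=s.positions)
            b.attrs["direction"] = s.direction
            b.attrs["plane_z"] = s.plane_z
            b.attrs["gradient"] = f.gradient
            b.attrs["bias"] = f.bias


def lead_field_from_hdf5(path) -> LeadField:
    import h5py

    with h5py.File(path, "r") as h5:
        g = h5["grid"]
        grid = VoxelGrid(origin=g.attrs["origin"],
                         spacing=float(g.attrs["spacing"]),
                         shape=tuple(int(s) for s in g.attrs["shape"]),
                         mask=g["mask"][...])
        sensors, fields = [], []
        i = 0
        while f"block{i}" in h5:
            b = h5[f"block{i}"]
            sensors.append(SensorArray(positions=b["sensor_positions"][...],
                                       direction=b.attrs["direction"],
                                       plane_z=float(b.attrs["plane_z"])))
            fields.append(AppliedFieldZ(gradient=float(b.attrs["gradient"]),
                                        bias=float(b.attrs["bias"])))
            i += 1
        return LeadField(matrix=h5["matrix"][...], grid=grid,
                         sensors=tuple(sensors), fields=tuple(fields),
                         block_offsets=tuple(int(o) for o in
                                             h5.attrs["block_offsets"]),
                         kappa=float(h5.attrs["kappa"]))
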