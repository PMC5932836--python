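"""Minimal legacy-VTK (ASCII structured points) export for voxel data.

Cell-centered scalar/vector fields on the uniform voxel grid are written in
the plain-text legacy format, loadable by ParaView and other standard VTK
readers.
"""

from __future__ import annotations

import numpy as np

from .geometry import VoxelDomain

__all__ = ["write_structured_points"]


def write_structured_points(path, domain: VoxelDomain,
                            cell_scalars: dict[str, np.ndarray] | None = None,
                            cell_vectors: dict[str, np.ndarray] | None = None) -> None:
    """Write the voxel grid with cell data as a legacy VTK file (mm units)."""
    nx, ny, nz = domain.shape
    n_cells = nx * ny * nz
    try:
        f = open(path, "w")
    except OSError as e:
        raise OSError(f"cannot write VTK file {path!r}: {e}") from e
    with f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("aortohemo voxel domain\nASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        f.write(f"ORIGIN {domain.origin[0]} {domain.origin[1]} {domain.origin[2]}\n")
        f.write(f"SPACING {domain.h} {domain.h} {domain.h}\n")
        f.write(f"CELL_DATA {n_cells}\n")
        scal = {"fluid": domain.fluid.astype(np.int8)}
        scal.update(cell_scalars or {})
        for name, arr in scal.items():
            if arr.shape != domain.shape:
                raise ValueError(f"cell scalar {name!r} has shape {arr.shape}, "
                                 f"expected {domain.shape}")
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, np.asarray(arr, dtype=float).ravel(order="F"), fmt="%.6g")
        for name, arr in (cell_vectors or {}).items():
            if arr.shape != (*domain.shape, 3):
                raise ValueError(f"cell vector {name!r} has shape {arr.shape}, "
                                 f"expected {(*domain.shape, 3)}")
            f.write(f"VECTORS {name} float\n")
            flat = np.stack([np.asarray(arr[..., c], dtype=float).ravel(order="F")
                             for c in range(3)], axis=1)
            np.savetxt(f, flat, fmt="%.6g")
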