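"""Legacy-VTK structured-points output for field inspection in ParaView."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_structured_points"]


def write_structured_points(
    path: str | Path,
    name: str,
    field: np.ndarray,
    *,
    origin: tuple[float, float] = (0.0, 0.0),
    spacing: float = 1.0,
    fill: float = -1.0,
) -> Path:
    """Write one (nx, ny) scalar cell field as an ASCII legacy VTK file.

    NaN cells (outside the planform) are replaced by ``fill``.  One scalar
    per file; the z dimension is a single layer.
    """
    path = Path(path)
    a = np.asarray(field, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D field")
    nx, ny = a.shape
    a = np.where(np.isfinite(a), a, fill)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} 0\n")
        fh.write(f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}\n")
        fh.write(f"CELL_DATA {nx * ny}\n")
        fh.write(f"SCALARS {name} double 1\n")
        fh.write("LOOKUP_TABLE default\n")
        # VTK cell order: x fastest
        for j in range(ny):
            row = " ".join(f"{a[i, j]:.9g}" for i in range(nx))
            fh.write(row + "\n")
    return path
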