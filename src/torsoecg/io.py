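"""File output: legacy-VTK structured-points snapshots and trace CSV helpers.

The VTK writer emits ASCII ``STRUCTURED_POINTS`` files readable by ParaView
and friends; one scalar array per field (NaN outside the domain is written
as a large sentinel readable by the threshold filter).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = ["write_vtk_structured_points"]

_NAN_SENTINEL = 9.999e29


def write_vtk_structured_points(path, arrays: Mapping[str, np.ndarray],
                                origin=(0.0, 0.0, 0.0), spacing=1.0,
                                title: str = "torsoecg fields") -> None:
    """Write 3D scalar arrays on a common regular grid to one legacy-VTK file."""
    arrays = dict(arrays)
    if not arrays:
        raise ValueError("no arrays to write")
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError(f"arrays differ in shape: {shapes}")
    nx, ny, nz = shapes.pop()
    sp = (spacing, spacing, spacing) if np.isscalar(spacing) else tuple(spacing)

    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {origin[0]} {origin[1]} {origin[2]}",
        f"SPACING {sp[0]} {sp[1]} {sp[2]}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in arrays.items():
        data = np.asarray(arr, dtype=float)
        data = np.where(np.isfinite(data), data, _NAN_SENTINEL)
        # VTK structured points iterate x fastest
        flat = data.transpose(2, 1, 0).ravel()
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")
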