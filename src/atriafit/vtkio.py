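"""Minimal legacy-ASCII VTK POLYDATA writer for meshes, point clouds and
their scalar fields (LAT maps, CV fields, fitted markers, conductivity
bins).  Writer only; files open in ParaView or any VTK-based viewer."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_polydata", "write_point_cloud"]


def _fmt_array(a: np.ndarray) -> str:
    return "\n".join(" ".join(f"{x:.9g}" for x in row) for row in np.atleast_2d(a))


def write_polydata(
    path,
    points_mm: np.ndarray,
    triangles: np.ndarray | None = None,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write a legacy VTK 2.0 ASCII POLYDATA file.

    ``point_data`` / ``cell_data`` map field names to 1D scalar arrays
    (NaN kept as nan; VTK viewers treat them as blanked values).
    """
    points = np.asarray(points_mm, dtype=float)
    lines = [
        "# vtk DataFile Version 2.0",
        "atriafit surface export",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} float",
        _fmt_array(points),
    ]
    if triangles is not None:
        tris = np.asarray(triangles, dtype=int)
        lines.append(f"POLYGONS {len(tris)} {4 * len(tris)}")
        lines.append("\n".join("3 " + " ".join(map(str, t)) for t in tris))
    else:
        lines.append(f"VERTICES {len(points)} {2 * len(points)}")
        lines.append("\n".join(f"1 {i}" for i in range(len(points))))

    def scalar_block(name: str, values: np.ndarray) -> list[str]:
        v = np.asarray(values, dtype=float)
        return [
            f"SCALARS {name} float 1",
            "LOOKUP_TABLE default",
            "\n".join(f"{x:.9g}" for x in v),
        ]

    if point_data:
        lines.append(f"POINT_DATA {len(points)}")
        for name, values in point_data.items():
            if len(values) != len(points):
                raise ValueError(f"point field {name!r} has wrong length")
            lines.extend(scalar_block(name, values))
    if cell_data:
        n_cells = len(triangles) if triangles is not None else len(points)
        lines.append(f"CELL_DATA {n_cells}")
        for name, values in cell_data.items():
            if len(values) != n_cells:
                raise ValueError(f"cell field {name!r} has wrong length")
            lines.extend(scalar_block(name, values))
    Path(path).write_text("\n".join(lines) + "\n")


def write_point_cloud(path, points_mm: np.ndarray, point_data: dict | None = None) -> None:
    """Electrode positions with per-point scalars (LAT, CV, markers)."""
    write_polydata(path, points_mm, triangles=None, point_data=point_data)
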