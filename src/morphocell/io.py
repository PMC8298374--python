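"""Writers for simulation artefacts: legacy-VTK fields, CSV time series,
cell boundary snapshots and JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import Mesh

__all__ = ["write_vtk", "write_timeseries_csv", "read_timeseries_csv",
           "write_cell_snapshots_csv", "write_json_summary",
           "write_vertex_table", "read_vertex_table"]


def write_vtk(path, mesh: Mesh, point_data: dict | None = None) -> Path:
    """Write the mesh and per-vertex fields as a legacy ASCII VTK file.

    Scalar fields are (n,) arrays; vector fields (n, 2) are padded with a
    zero z-component.
    """
    path = Path(path)
    n = mesh.n_vertices
    m = len(mesh.triangles)
    lines = [
        "# vtk DataFile Version 3.0",
        "morphocell field snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for x, y in mesh.vertices:
        lines.append(f"{x:.10g} {y:.10g} 0")
    lines.append(f"CELLS {m} {4 * m}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.10g} {v[1]:.10g} 0" for v in arr)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_timeseries_csv(path, series: dict) -> Path:
    """Write aligned per-step series (dict of 1-D arrays) as RFC-4180 CSV."""
    path = Path(path)
    pd.DataFrame(series).to_csv(path, index=False, lineterminator="\n")
    return path


def read_timeseries_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cell_snapshots_csv(path, snapshots) -> Path:
    """Cell boundary history: rows of (time, cell, node, x, y)."""
    rows = []
    for t, cells in snapshots:
        for ci, nodes in enumerate(cells):
            for j, (x, y) in enumerate(nodes):
                rows.append((t, ci, j, x, y))
    df = pd.DataFrame(rows, columns=["time", "cell", "node", "x", "y"])
    df.to_csv(Path(path), index=False, lineterminator="\n")
    return Path(path)


def write_vertex_table(path, mesh: Mesh) -> Path:
    df = pd.DataFrame(mesh.vertices, columns=["x", "y"])
    df.to_csv(Path(path), index=False, lineterminator="\n")
    return Path(path)


def read_vertex_table(path) -> np.ndarray:
    return pd.read_csv(path)[["x", "y"]].to_numpy()


def write_json_summary(path, summary: dict) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"unserialisable {type(o)}")

    path.write_text(json.dumps(summary, indent=2, sort_keys=True,
                               default=_default) + "\n")
    return path
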