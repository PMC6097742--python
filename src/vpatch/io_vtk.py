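"""Minimal legacy-ASCII VTK writer for triangle surface meshes.

Covers exactly what the pipeline exports: points, triangle cells, scalar
or 3-vector point data, scalar cell data.
"""

from __future__ import annotations

import numpy as np


def write_vtk(path: str, nodes: np.ndarray, tris: np.ndarray,
              point_data: dict | None = None,
              cell_data: dict | None = None,
              title: str = "vpatch surface") -> None:
    nodes = np.asarray(nodes, dtype=float)
    tris = np.asarray(tris, dtype=np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in p) for p in nodes]
    lines.append(f"CELLS {len(tris)} {4 * len(tris)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in tris]
    lines.append(f"CELL_TYPES {len(tris)}")
    lines += ["5"] * len(tris)

    def _emit(block: dict, n: int, kind: str) -> None:
        lines.append(f"{kind} {n}")
        for name, arr in block.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr.ravel())

    if point_data:
        _emit(point_data, len(nodes), "POINT_DATA")
    if cell_data:
        _emit(cell_data, len(tris), "CELL_DATA")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
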