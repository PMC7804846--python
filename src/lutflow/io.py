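"""File-format plumbing: Gmsh MSH 2.2, legacy VTK, CSV tables, metadata.

Geometry files are written in centimetres (stated in their headers); mesh
and field files are SI (metres, Pa, m/s).  Both mesh formats are plain
ASCII.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .flow_solver import FlowSolution
from .meshing import Mesh

__all__ = [
    "write_msh2",
    "write_vtk",
    "write_solution_vtk",
    "write_residuals_csv",
    "write_metadata",
]

_PHYS_IDS = {"inlet": 1, "outlet": 2, "wall": 3, "symmetry": 5}


def write_msh2(mesh: Mesh, path: str | Path) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII with tagged boundary lines."""
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(_PHYS_IDS) + 1)]
    for name, pid in _PHYS_IDS.items():
        lines.append(f'1 {pid} "{name}"')
    lines.append('2 4 "fluid"')
    lines.append("$EndPhysicalNames")
    lines += ["$Nodes", str(len(mesh.nodes))]
    for i, (x, y) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.12g} {y:.12g} 0")
    lines.append("$EndNodes")
    n_el = len(mesh.boundary_edges) + len(mesh.triangles)
    lines += ["$Elements", str(n_el)]
    eid = 1
    for (a, b), tag in zip(mesh.boundary_edges, mesh.boundary_tags):
        pid = _PHYS_IDS[str(tag)]
        lines.append(f"{eid} 1 2 {pid} {pid} {a + 1} {b + 1}")
        eid += 1
    for a, b, c in mesh.triangles:
        lines.append(f"{eid} 2 2 4 4 {a + 1} {b + 1} {c + 1}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def write_vtk(mesh: Mesh, path: str | Path,
              point_data: Mapping[str, np.ndarray] | None = None,
              cell_data: Mapping[str, np.ndarray] | None = None,
              title: str = "lutflow mesh") -> None:
    """Write a legacy-VTK ASCII unstructured grid with optional fields."""
    path = Path(path)
    out = ["# vtk DataFile Version 2.0", title, "ASCII",
           "DATASET UNSTRUCTURED_GRID",
           f"POINTS {len(mesh.nodes)} double"]
    for x, y in mesh.nodes:
        out.append(f"{x:.12g} {y:.12g} 0")
    m = len(mesh.triangles)
    out.append(f"CELLS {m} {4 * m}")
    for a, b, c in mesh.triangles:
        out.append(f"3 {a} {b} {c}")
    out.append(f"CELL_TYPES {m}")
    out.extend(["5"] * m)

    def _fields(block: Mapping[str, np.ndarray], kind: str, n: int):
        out.append(f"{kind} {n}")
        for name, arr in block.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 2:
                out.append(f"VECTORS {name} double")
                for vx, vy in arr:
                    out.append(f"{vx:.9g} {vy:.9g} 0")
            else:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out.extend(f"{v:.9g}" for v in arr)

    if point_data:
        _fields(point_data, "POINT_DATA", len(mesh.nodes))
    if cell_data:
        _fields(cell_data, "CELL_DATA", m)
    path.write_text("\n".join(out) + "\n")


def write_solution_vtk(solution: FlowSolution, mesh: Mesh, path: str | Path,
                       psi: np.ndarray | None = None) -> None:
    """Export the solved fields (p, velocity, speed, k, eps, psi) to VTK."""
    cell_data = {"p": solution.p,
                 "velocity": np.column_stack([solution.u, solution.v]),
                 "speed": solution.speed}
    if solution.k is not None:
        cell_data["k"] = solution.k
        cell_data["eps"] = solution.eps
        cell_data["mu_t"] = solution.mu_t
    point_data = {"psi": psi} if psi is not None else None
    write_vtk(mesh, path, point_data=point_data, cell_data=cell_data,
              title="lutflow solution (SI units)")


def write_residuals_csv(solution: FlowSolution, path: str | Path) -> None:
    import pandas as pd

    hist = {k: v for k, v in solution.residuals.items() if v}
    pd.DataFrame(hist).rename_axis("iteration").to_csv(Path(path))


def write_metadata(path: str | Path, **entries) -> None:
    """Echo the run configuration (JSON) so a run can be reproduced."""
    from dataclasses import asdict, is_dataclass

    def _clean(v):
        if is_dataclass(v) and not isinstance(v, type):
            return asdict(v)
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, Path):
            return str(v)
        return v

    payload = {k: _clean(v) for k, v in entries.items()}
    try:
        from importlib.metadata import version

        payload["lutflow_version"] = version("lutflow")
    except Exception:
        payload["lutflow_version"] = "unknown"
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
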