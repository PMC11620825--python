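"""Minimal ASCII VTU writer for field snapshots.

Writes the Q1 (corner-node) skeleton of the mesh as linear hexahedra with
point data (displacement, pore pressure), enough for inspection in ParaView.
"""

from __future__ import annotations

import numpy as np

# lexicographic corner order -> VTK hexahedron order
_VTK_ORDER = [0, 1, 3, 2, 4, 5, 7, 6]


def write_vtu(mesh, path, point_data: dict | None = None) -> None:
    """Write corner nodes + hex cells + per-pressure-node point data."""
    pts = mesh.coords[mesh.pnode_unode]
    cells = mesh.hex8[:, _VTK_ORDER]
    npts, ncel = len(pts), len(cells)
    point_data = point_data or {}

    def arr(a, fmt="%.9g"):
        return "\n".join(" ".join(fmt % v for v in np.atleast_1d(row))
                         for row in a)

    chunks = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncel}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(pts), "</DataArray>", "</Points>",
        "<Cells>",
        '<DataArray type="Int32" Name="connectivity" format="ascii">',
        arr(cells, "%d"), "</DataArray>",
        '<DataArray type="Int32" Name="offsets" format="ascii">',
        arr(8 * np.arange(1, ncel + 1)[:, None], "%d"), "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        arr(np.full((ncel, 1), 12), "%d"), "</DataArray>",
        "</Cells>",
        "<PointData>",
    ]
    for name, data in point_data.items():
        data = np.asarray(data)
        ncomp = 1 if data.ndim == 1 else data.shape[1]
        chunks.append(f'<DataArray type="Float64" Name="{name}" '
                      f'NumberOfComponents="{ncomp}" format="ascii">')
        chunks.append(arr(data))
        chunks.append("</DataArray>")
    chunks += ["</PointData>", "</Piece>", "</UnstructuredGrid>",
               "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(chunks))


def snapshot_point_data(mesh, snapshot) -> dict:
    """Displacement and pressure fields of a snapshot at the corner nodes."""
    return {"displacement_m": snapshot.u[mesh.pnode_unode],
            "pore_pressure_Pa": snapshot.p}
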