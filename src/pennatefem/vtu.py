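"""Minimal ASCII VTU (VTK XML unstructured grid) writer for hex meshes.

Writes point/cell data arrays alongside the hexahedral connectivity so
states can be inspected in ParaView.  Only the small subset of the format
needed here is produced (appended/binary encodings are deliberately not
supported).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import HexMesh

__all__ = ["write_vtu"]

_VTK_HEXAHEDRON = 12


def _data_array(name, data, n_components):
    body = "\n".join(" ".join(f"{v:.9g}" for v in np.atleast_1d(row))
                     for row in np.asarray(data))
    return (f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{n_components}" format="ascii">\n'
            f"{body}\n</DataArray>")


def write_vtu(path, mesh: HexMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh (optionally deformed via point_data['u']) plus data
    arrays to ``path``."""
    point_data = point_data or {}
    cell_data = cell_data or {}
    npts, ncel = mesh.n_nodes, mesh.n_cells
    pts = "\n".join(" ".join(f"{v:.9g}" for v in p)
                    for p in mesh.node_coords)
    conn = "\n".join(" ".join(str(i) for i in c) for c in mesh.hexes)
    offsets = " ".join(str(8 * (i + 1)) for i in range(ncel))
    types = " ".join(str(_VTK_HEXAHEDRON) for _ in range(ncel))

    pdata = "\n".join(
        _data_array(k, v, 3 if np.asarray(v).ndim == 2 else 1)
        for k, v in point_data.items())
    cdata = "\n".join(
        _data_array(k, v, 3 if np.asarray(v).ndim == 2 else 1)
        for k, v in cell_data.items())

    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{npts}" NumberOfCells="{ncel}">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">
{pts}
</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{conn}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{offsets}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{types}
</DataArray>
</Cells>
<PointData>
{pdata}
</PointData>
<CellData>
{cdata}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    Path(path).write_text(xml)
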