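"""Mesh and field export / import: ASCII VTU (VTK XML) and Gmsh MSH v2.2.

Quadratic triangles map to VTK cell type 22 and quadratic tetrahedra to
type 24 (matching node ordering); region labels travel as cell data plus a
name table in the field data, and named facet/node sets are preserved in
MSH physical groups only loosely (facet sets are re-derivable from the
geometry, so VTU round trips carry nodes, cells, regions, and fields).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .errors import MeshError
from .meshing import RegionTaggedMesh

__all__ = ["write_vtu", "read_vtu", "export_fields", "write_msh", "read_msh"]

_VTK_CELL = {6: 22, 10: 24}   # tri6, tet10
_GMSH_CELL = {6: 9, 10: 11}


def _fmt(a: np.ndarray) -> str:
    a = np.asarray(a)
    if a.dtype.kind == "f":
        return "\n".join(" ".join(repr(float(x)) for x in row)
                         for row in np.atleast_2d(a))
    return "\n".join(" ".join(str(int(x)) for x in row)
                     for row in np.atleast_2d(a))


def write_vtu(path, mesh: RegionTaggedMesh, point_data=None, cell_data=None):
    """Write an ASCII .vtu with optional nodal / per-element arrays.

    Nodal vectors are padded to three components (2-D meshes embed in the
    y = 0 ... the (x, z) plane maps to VTK (x, y)).
    """
    nodes = mesh.nodes
    if mesh.dim == 2:
        xyz = np.column_stack([nodes, np.zeros(len(nodes))])
    else:
        xyz = nodes
    ctype = _VTK_CELL[mesh.elements.shape[1]]

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece",
                          NumberOfPoints=str(mesh.n_nodes),
                          NumberOfCells=str(mesh.n_elements))

    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64",
                       NumberOfComponents="3", format="ascii")
    da.text = _fmt(xyz)

    cells = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(cells, "DataArray", type="Int64",
                         Name="connectivity", format="ascii")
    conn.text = _fmt(mesh.elements)
    offs = ET.SubElement(cells, "DataArray", type="Int64", Name="offsets",
                         format="ascii")
    offs.text = _fmt(np.cumsum(np.full(mesh.n_elements,
                                       mesh.elements.shape[1]))[:, None])
    typ = ET.SubElement(cells, "DataArray", type="UInt8", Name="types",
                        format="ascii")
    typ.text = _fmt(np.full((mesh.n_elements, 1), ctype))

    pd = ET.SubElement(piece, "PointData")
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 2:
            arr = np.column_stack([arr, np.zeros(len(arr))])
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        d = ET.SubElement(pd, "DataArray", type="Float64", Name=name,
                          NumberOfComponents=str(ncomp), format="ascii")
        d.text = _fmt(arr if arr.ndim == 2 else arr[:, None])

    cd = ET.SubElement(piece, "CellData")
    rid = ET.SubElement(cd, "DataArray", type="Int64", Name="region_id",
                        NumberOfComponents="1", format="ascii")
    rid.text = _fmt(mesh.region_ids[:, None])
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr, dtype=float)
        flat = arr.reshape(len(arr), -1)
        d = ET.SubElement(cd, "DataArray", type="Float64", Name=name,
                          NumberOfComponents=str(flat.shape[1]),
                          format="ascii")
        d.text = _fmt(flat)

    fd = ET.SubElement(grid, "FieldData")
    names = ET.SubElement(fd, "Array", Name="region_names", format="ascii")
    names.text = ";".join(mesh.region_names)
    dim = ET.SubElement(fd, "Array", Name="mesh_dim", format="ascii")
    dim.text = str(mesh.dim)

    ET.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8")
    return Path(path)


def read_vtu(path):
    """Read a .vtu written by :func:`write_vtu`.

    Returns (mesh, point_data, cell_data); facet/node sets are not stored
    in the file and come back empty.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshError(f"{path}: not an unstructured VTK XML file")

    def parse(el, dtype=float):
        return np.array(el.text.split(), dtype=dtype)

    pts = parse(piece.find("Points/DataArray")).reshape(-1, 3)
    conn = parse(piece.find("Cells/DataArray[@Name='connectivity']"),
                 float).astype(np.int64)
    types = parse(piece.find("Cells/DataArray[@Name='types']"),
                  float).astype(int)
    ctype = types[0]
    npc = {22: 6, 24: 10}.get(ctype)
    if npc is None:
        raise MeshError(f"unsupported VTK cell type {ctype}")
    elements = conn.reshape(-1, npc)

    fd = root.find(".//FieldData")
    names = tuple(fd.find("Array[@Name='region_names']").text.split(";"))
    dim = int(fd.find("Array[@Name='mesh_dim']").text)
    nodes = pts[:, [0, 1]] if dim == 2 else pts

    point_data, cell_data = {}, {}
    region_ids = np.zeros(len(elements), dtype=np.int64)
    for da in piece.findall("PointData/DataArray"):
        ncomp = int(da.get("NumberOfComponents", "1"))
        arr = parse(da).reshape(-1, ncomp)
        point_data[da.get("Name")] = arr[:, 0] if ncomp == 1 else arr
    for da in piece.findall("CellData/DataArray"):
        ncomp = int(da.get("NumberOfComponents", "1"))
        arr = parse(da).reshape(-1, ncomp)
        arr = arr[:, 0] if ncomp == 1 else arr
        if da.get("Name") == "region_id":
            region_ids = arr.astype(np.int64)
        else:
            cell_data[da.get("Name")] = arr
    mesh = RegionTaggedMesh(dim=dim, nodes=nodes, elements=elements,
                            region_ids=region_ids, region_names=names)
    return mesh, point_data, cell_data


def export_fields(solution, mesh: RegionTaggedMesh, path):
    """Write displacement, Cauchy stress, von Mises, and principal strain.

    Per-element tensors are quadrature averages; the written von Mises
    field is recomputable from the written stress components.
    """
    from .postprocess import element_max_principal_strain, element_von_mises

    sig = solution.cauchy_stress_qp().mean(axis=1)      # (ne, 3, 3)
    iu = np.triu_indices(3)
    stress_voigt = sig[:, iu[0], iu[1]]                 # xx xy xz yy yz zz
    cell_data = {
        "cauchy_stress": stress_voigt,
        "von_mises": element_von_mises(solution),
        "max_principal_log_strain": element_max_principal_strain(solution),
    }
    return write_vtu(path, mesh,
                     point_data={"displacement": solution.displacements},
                     cell_data=cell_data)


def write_msh(path, mesh: RegionTaggedMesh):
    """Write a Gmsh MSH v2.2 ASCII file (nodes mm; regions as physical
    and elementary tags)."""
    nodes = mesh.nodes
    if mesh.dim == 2:
        nodes = np.column_stack([nodes, np.zeros(len(nodes))])
    etype = _GMSH_CELL[mesh.elements.shape[1]]
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(mesh.region_names))]
    for i, name in enumerate(mesh.region_names):
        lines.append(f"{mesh.dim} {i + 1} \"{name}\"")
    lines += ["$EndPhysicalNames", "$Nodes", str(len(nodes))]
    for i, p in enumerate(nodes, start=1):
        lines.append(f"{i} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}")
    lines += ["$EndNodes", "$Elements", str(mesh.n_elements)]
    for i, (cell, rid) in enumerate(zip(mesh.elements, mesh.region_ids),
                                    start=1):
        tags = f"2 {rid + 1} {rid + 1}"
        lines.append(f"{i} {etype} {tags} "
                     + " ".join(str(n + 1) for n in cell))
    lines += ["$EndElements", ""]
    Path(path).write_text("\n".join(lines), encoding="utf-8")
    return Path(path)


def read_msh(path):
    """Read a v2.2 MSH written by :func:`write_msh` (tri6 / tet10 only)."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    it = iter(text)
    names = {}
    nodes = []
    cells, rids = [], []
    for line in it:
        if line == "$PhysicalNames":
            n = int(next(it))
            for _ in range(n):
                dim, tag, name = next(it).split(maxsplit=2)
                names[int(tag)] = name.strip('"')
            next(it)
        elif line == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(x) for x in parts[1:4]])
            next(it)
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                rids.append(int(parts[3]) - 1)
                conn = [int(x) - 1 for x in parts[3 + ntags:]]
                if etype not in (9, 11):
                    raise MeshError(f"unsupported MSH element type {etype}")
                cells.append(conn)
            next(it)
    nodes = np.asarray(nodes)
    cells = np.asarray(cells, dtype=np.int64)
    rids = np.asarray(rids, dtype=np.int64)
    dim = 2 if cells.shape[1] == 6 else 3
    if dim == 2:
        nodes = nodes[:, :2]
    region_names = tuple(names[i + 1] for i in range(len(names)))
    return RegionTaggedMesh(dim=dim, nodes=nodes, elements=cells,
                            region_ids=rids, region_names=region_names)
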