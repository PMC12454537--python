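"""File-format glue: streamlines (TRK/TCK), voxel maps (NIfTI-1), meshes
(Gmsh MSH / VTU), and CSV/JSON tables.

Streamline and NIfTI I/O go through nibabel; the Gmsh and VTK writers emit
plain ASCII (MSH 2.2 and XML .vtu), formats small enough to implement
directly and readable by the usual downstream tools (gmsh, ParaView,
meshio).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import streamlines as nib_streamlines

from .mesh import REGIONS, TaggedTetMesh
from .tract_fields import StreamlineSet, VoxelGrid

__all__ = [
    "save_streamlines",
    "load_streamlines",
    "save_voxel_map",
    "load_voxel_map",
    "save_voxel_summary_csv",
    "write_msh",
    "read_msh",
    "write_vtu",
    "read_vtu",
    "write_json",
]


# --- streamlines -----------------------------------------------------------


def save_streamlines(path, sset: StreamlineSet, grid: VoxelGrid | None = None):
    """Write TRK or TCK (by extension), coordinates in world mm."""
    path = Path(path)
    affine = grid.nifti_affine if grid is not None else np.eye(4)
    tractogram = nib_streamlines.Tractogram(
        list(sset), affine_to_rasmm=np.eye(4)
    )
    if path.suffix == ".trk":
        header = {}
        if grid is not None:
            header[nib_streamlines.trk.Field.VOXEL_TO_RASMM] = affine
            header[nib_streamlines.trk.Field.VOXEL_SIZES] = tuple(grid.spacing)
            header[nib_streamlines.trk.Field.DIMENSIONS] = tuple(grid.shape)
        nib_streamlines.save(tractogram, str(path), header=header)
    elif path.suffix == ".tck":
        nib_streamlines.save(tractogram, str(path))
    else:
        raise ValueError(f"unsupported streamline format {path.suffix!r}")


def load_streamlines(path) -> StreamlineSet:
    tf = nib_streamlines.load(str(path))
    return StreamlineSet(
        [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines],
        validate=False,
    )


# --- voxel maps ------------------------------------------------------------


def save_voxel_map(path, data: np.ndarray, grid: VoxelGrid, dtype=np.float32):
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), grid.nifti_affine)
    zooms = tuple(grid.spacing) + (1.0,) * (data.ndim - 3)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_voxel_map(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    A = img.affine
    spacing = tuple(np.abs(np.diag(A)[:3]))
    origin = tuple(A[:3, 3] - 0.5 * np.abs(np.diag(A)[:3]))
    grid = VoxelGrid(img.shape[:3], spacing, origin)
    return np.asarray(img.dataobj), grid


def save_voxel_summary_csv(path, grid: VoxelGrid, count, divergence):
    """Per-voxel table (index triplet, K, D) for voxels with any signal."""
    K = np.asarray(count)
    D = np.asarray(divergence)
    sel = (K != 0) | (D != 0)
    idx = np.argwhere(sel)
    pd.DataFrame(
        {
            "i": idx[:, 0],
            "j": idx[:, 1],
            "k": idx[:, 2],
            "count": K[sel],
            "divergence": D[sel],
        }
    ).to_csv(path, index=False)


# --- meshes ----------------------------------------------------------------


def write_msh(path, mesh: TaggedTetMesh):
    """Gmsh MSH 2.2 ASCII with region ids as physical/elementary tags."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(REGIONS))]
    for rid, name in REGIONS.items():
        lines.append(f'3 {rid} "{name}"')
    lines.append("$EndPhysicalNames")
    lines += ["$Nodes", str(mesh.n_nodes)]
    for i, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {p[0]:.16g} {p[1]:.16g} {p[2]:.16g}")
    lines.append("$EndNodes")
    lines += ["$Elements", str(mesh.n_elements)]
    for e, (tet, rid) in enumerate(zip(mesh.elements, mesh.region), start=1):
        n = " ".join(str(v + 1) for v in tet)
        lines.append(f"{e} 4 2 {rid} {rid} {n}")
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def read_msh(path) -> TaggedTetMesh:
    """Read back the MSH 2.2 files written by :func:`write_msh`."""
    text = Path(path).read_text().splitlines()
    it = iter(text)
    nodes, elements, region = [], [], []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(x) for x in parts[1:4]])
        elif line.strip() == "$Elements":
            m = int(next(it))
            for _ in range(m):
                parts = next(it).split()
                if parts[1] != "4":
                    continue
                ntags = int(parts[2])
                region.append(int(parts[3]))
                elements.append(
                    [int(v) - 1 for v in parts[3 + ntags : 7 + ntags]]
                )
    return TaggedTetMesh(
        nodes=np.asarray(nodes),
        elements=np.asarray(elements, dtype=np.int64),
        region=np.asarray(region, dtype=np.int64),
    )


def _ascii_array(a, fmt="{:.9g}") -> str:
    return " ".join(fmt.format(v) for v in np.asarray(a).ravel())


def write_vtu(
    path,
    mesh: TaggedTetMesh,
    point_data: dict | None = None,
    cell_data: dict | None = None,
):
    """XML ASCII VTK UnstructuredGrid with linear tetrahedra.

    ``point_data``/``cell_data`` map names to per-node / per-element arrays
    (scalars or 3-vectors).  The region labels are always written as cell
    data ``region``.
    """
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region)
    point_data = dict(point_data or {})
    n, m = mesh.n_nodes, mesh.n_elements

    def data_array(name, arr, indent):
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        typ = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        return (
            f'{indent}<DataArray type="{typ}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
            f"{indent}  {_ascii_array(arr)}\n{indent}</DataArray>"
        )

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "      <Points>",
        data_array("Points", mesh.nodes, "        "),
        "      </Points>",
        "      <Cells>",
        data_array("connectivity", mesh.elements.astype(np.int64), "        "),
        data_array(
            "offsets", 4 * np.arange(1, m + 1, dtype=np.int64), "        "
        ),
        data_array("types", np.full(m, 10, dtype=np.int64), "        "),
        "      </Cells>",
    ]
    if point_data:
        parts.append("      <PointData>")
        for name, arr in point_data.items():
            parts.append(data_array(name, arr, "        "))
        parts.append("      </PointData>")
    parts.append("      <CellData>")
    for name, arr in cell_data.items():
        parts.append(data_array(name, arr, "        "))
    parts.append("      </CellData>")
    parts += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts) + "\n")


def read_vtu(path) -> tuple[TaggedTetMesh, dict, dict]:
    """Read the ASCII VTU files written by :func:`write_vtu`."""
    from lxml import etree

    root = etree.parse(str(path)).getroot()
    piece = root.find(".//Piece")

    def parse(elem):
        arr = np.fromstring(elem.text.strip(), sep=" ")
        ncomp = int(elem.get("NumberOfComponents", "1"))
        if "Int" in elem.get("type", ""):
            arr = arr.astype(np.int64)
        return arr.reshape(-1, ncomp) if ncomp > 1 else arr

    points = parse(piece.find("Points/DataArray"))
    cells = {
        e.get("Name"): parse(e) for e in piece.findall("Cells/DataArray")
    }
    conn = cells["connectivity"].astype(np.int64).reshape(-1, 4)
    point_data, cell_data = {}, {}
    for tag, store in (("PointData", point_data), ("CellData", cell_data)):
        node = piece.find(tag)
        if node is not None:
            for e in node.findall("DataArray"):
                store[e.get("Name")] = parse(e)
    region = cell_data.pop("region", np.ones(len(conn), dtype=np.int64))
    mesh = TaggedTetMesh(
        nodes=points, elements=conn, region=region.astype(np.int64)
    )
    return mesh, point_data, cell_data


def export_mask_surface_vtu(path, mask) -> int:
    """Triangulated iso-surface of a binary voxel mask as a VTU file.

    Marching cubes at the 0.5 level in world coordinates; returns the
    number of triangles written.  Intended as meshing input for the
    detected aponeurosis sheet.
    """
    from skimage import measure

    data = np.pad(mask.data.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(data, level=0.5)
    # padded index space -> continuous index -> world
    verts = (verts - 1.0 + 0.5) @ np.diag(mask.grid.spacing) + np.asarray(
        mask.grid.origin
    )
    n, m = len(verts), len(faces)

    def arr(a, fmt="{:.9g}"):
        return " ".join(fmt.format(v) for v in np.asarray(a).ravel())

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "      <Points>",
        f'        <DataArray type="Float64" Name="Points" NumberOfComponents="3" format="ascii">',
        f"          {arr(verts)}",
        "        </DataArray>",
        "      </Points>",
        "      <Cells>",
        f'        <DataArray type="Int64" Name="connectivity" NumberOfComponents="1" format="ascii">',
        f"          {arr(faces.astype(np.int64), '{:d}')}",
        "        </DataArray>",
        f'        <DataArray type="Int64" Name="offsets" NumberOfComponents="1" format="ascii">',
        f"          {arr(3 * np.arange(1, m + 1), '{:d}')}",
        "        </DataArray>",
        f'        <DataArray type="Int64" Name="types" NumberOfComponents="1" format="ascii">',
        f"          {arr(np.full(m, 5), '{:d}')}",
        "        </DataArray>",
        "      </Cells>",
        "    </Piece>",
        "  </UnstructuredGrid>",
        "</VTKFile>",
    ]
    Path(path).write_text("\n".join(parts) + "\n")
    return m


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
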