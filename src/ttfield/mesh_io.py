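"""Text-format mesh and field I/O: Gmsh MSH 2.2 ASCII and legacy VTK.

Tissue labels travel as integer cell data named ``tissue`` (physical tags
in MSH, CELL_DATA in VTK); boundary patches are written as tagged surface
triangles in MSH.  Legacy VTK export can additionally carry solution fields
(``V_volts`` point data; ``E_Vpm``, ``normE_Vpm``, ``J_Apm2`` cell data)
and symmetric conductivity tensors as 6-component cell data.

Both formats are simple line-oriented ASCII; readers accept files produced
by standard meshers as long as tetrahedra carry a tissue tag.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .mesh import TISSUE_NAMES, TetMesh

__all__ = ["write_msh", "read_msh", "write_vtk", "read_vtk"]


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2 ASCII
# ---------------------------------------------------------------------------

def write_msh(path: str | Path, mesh: TetMesh) -> None:
    """Write mesh as Gmsh MSH v2.2 ASCII.

    Tets are element type 4 with the tissue code as physical tag; boundary
    patches are triangles (type 2) with physical tags 1000, 1001, ... in
    patch-name order, names recorded in ``$PhysicalNames``.
    """
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]

    patch_names = sorted(mesh.boundary_patches)
    names = [
        (3, int(code), name)
        for code, name in sorted(mesh.label_names.items())
        if code in set(mesh.tet_label.tolist())
    ] + [(2, 1000 + i, name) for i, name in enumerate(patch_names)]
    lines += ["$PhysicalNames", str(len(names))]
    lines += [f'{dim} {tag} "{name}"' for dim, tag, name in names]
    lines += ["$EndPhysicalNames"]

    lines += ["$Nodes", str(len(mesh.nodes))]
    lines += [
        f"{i + 1} {x:.10g} {y:.10g} {z:.10g}"
        for i, (x, y, z) in enumerate(mesh.nodes)
    ]
    lines += ["$EndNodes"]

    n_tri = sum(len(t) for t in mesh.boundary_patches.values())
    lines += ["$Elements", str(len(mesh.tets) + n_tri)]
    eid = 1
    for i, name in enumerate(patch_names):
        tag = 1000 + i
        for tri in mesh.boundary_patches[name]:
            lines.append(
                f"{eid} 2 2 {tag} {tag} {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}"
            )
            eid += 1
    for tet, lab in zip(mesh.tets, mesh.tet_label):
        lines.append(
            f"{eid} 4 2 {lab} {lab} {tet[0] + 1} {tet[1] + 1} {tet[2] + 1} {tet[3] + 1}"
        )
        eid += 1
    lines += ["$EndElements", ""]
    path.write_text("\n".join(lines))


def read_msh(path: str | Path) -> TetMesh:
    """Read a Gmsh MSH v2.2 ASCII file written by :func:`write_msh` or a
    compatible mesher; the first element tag is taken as the tissue code for
    tets and as the patch id for boundary triangles."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    nodes, tets, labels = [], [], []
    tris: dict[int, list] = {}
    phys: dict[tuple[int, int], str] = {}
    for line in it:
        key = line.strip()
        if key == "$MeshFormat":
            ver = next(it).split()[0]
            if not ver.startswith("2."):
                raise ValueError(f"unsupported MSH version {ver}")
        elif key == "$PhysicalNames":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split(maxsplit=2)
                phys[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')
        elif key == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(v) for v in parts[1:4]])
        elif key == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = [int(v) for v in next(it).split()]
                etype, ntags = parts[1], parts[2]
                tag = parts[3] if ntags else 0
                conn = parts[3 + ntags :]
                if etype == 4:
                    tets.append(conn)
                    labels.append(tag)
                elif etype == 2:
                    tris.setdefault(tag, []).append(conn)
    if not tets:
        raise ValueError(f"{path}: no tetrahedra found")
    label_names = dict(TISSUE_NAMES)
    label_names.update({tag: nm for (dim, tag), nm in phys.items() if dim == 3})
    patches = {
        phys.get((2, tag), f"patch{tag}"): np.asarray(t, dtype=np.int64) - 1
        for tag, t in tris.items()
    }
    return TetMesh(
        np.asarray(nodes),
        np.asarray(tets, dtype=np.int64) - 1,
        np.asarray(labels, dtype=np.int64),
        label_names=label_names,
        boundary_patches=patches,
    )


# ---------------------------------------------------------------------------
# Legacy VTK ASCII (unstructured grid)
# ---------------------------------------------------------------------------

def _sym6(tensors: np.ndarray) -> np.ndarray:
    # xx yy zz xy yz xz, the VTK symmetric-tensor ordering
    return np.column_stack(
        [tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2],
         tensors[:, 0, 1], tensors[:, 1, 2], tensors[:, 0, 2]]
    )


def write_vtk(
    path: str | Path,
    mesh: TetMesh,
    point_data: Mapping[str, np.ndarray] | None = None,
    cell_data: Mapping[str, np.ndarray] | None = None,
    solution=None,
    conductivity=None,
) -> None:
    """Write mesh (+ optional fields) as a legacy VTK unstructured grid.

    ``solution`` (a :class:`~ttfield.fem.Solution`) adds ``V_volts`` point
    data and ``E_Vpm`` / ``normE_Vpm`` / ``J_Apm2`` cell data;
    ``conductivity`` adds ``sigma_Spm`` as 6-component symmetric tensors.
    The ``tissue`` cell array is always written.
    """
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    if solution is not None:
        point_data["V_volts"] = solution.V
        cell_data["E_Vpm"] = solution.E
        cell_data["normE_Vpm"] = solution.norm_E()
        cell_data["J_Apm2"] = solution.J
    if conductivity is not None:
        cell_data["sigma_Spm"] = _sym6(conductivity.tensors)
    cell_data["tissue"] = mesh.tet_label

    out = ["# vtk DataFile Version 3.0", "ttfield mesh", "ASCII",
           "DATASET UNSTRUCTURED_GRID"]
    out.append(f"POINTS {len(mesh.nodes)} double")
    out += [f"{x:.10g} {y:.10g} {z:.10g}" for x, y, z in mesh.nodes]
    m = len(mesh.tets)
    out.append(f"CELLS {m} {5 * m}")
    out += [f"4 {a} {b} {c} {d}" for a, b, c, d in mesh.tets]
    out.append(f"CELL_TYPES {m}")
    out += ["10"] * m

    def emit(block: str, n: int, data: Mapping[str, np.ndarray]) -> None:
        if not data:
            return
        out.append(f"{block} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                out.append(f"SCALARS {name} {dtype} 1")
                out.append("LOOKUP_TABLE default")
                out.extend(f"{v}" for v in arr)
            elif arr.shape[1] == 3:
                out.append(f"VECTORS {name} double")
                out.extend(f"{a:.10g} {b:.10g} {c:.10g}" for a, b, c in arr)
            else:  # 6-component symmetric tensor rows
                out.append(f"FIELD {name}_field 1")
                out.append(f"{name} {arr.shape[1]} {len(arr)} double")
                out.extend(" ".join(f"{v:.10g}" for v in row) for row in arr)

    emit("POINT_DATA", len(mesh.nodes), point_data)
    emit("CELL_DATA", m, cell_data)
    Path(path).write_text("\n".join(out) + "\n")


def read_vtk(path: str | Path) -> TetMesh:
    """Read a legacy VTK unstructured grid with a ``tissue`` cell array."""
    lines = Path(path).read_text().split("\n")
    i, npts, nodes, cells, tissue = 0, 0, None, None, None
    ncells = 0
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "POINTS":
            npts = int(tok[1])
            vals = " ".join(lines[i + 1 : i + 1 + npts]).split()
            nodes = np.asarray(vals, dtype=float).reshape(npts, 3)
            i += npts + 1
        elif tok[0] == "CELLS":
            ncells = int(tok[1])
            rows = [lines[i + 1 + k].split() for k in range(ncells)]
            if any(r[0] != "4" for r in rows):
                raise ValueError("only tetrahedral (4-node) cells are supported")
            cells = np.asarray([r[1:5] for r in rows], dtype=np.int64)
            i += ncells + 1
        elif tok[0] == "SCALARS" and tok[1] == "tissue":
            vals = " ".join(lines[i + 2 : i + 2 + ncells]).split()
            tissue = np.asarray(vals[:ncells], dtype=float).astype(np.int64)
            i += ncells + 2
        else:
            i += 1
    if nodes is None or cells is None:
        raise ValueError(f"{path}: not a legacy VTK unstructured grid")
    if tissue is None:
        raise ValueError(f"{path}: missing 'tissue' cell data")
    return TetMesh(nodes, cells, tissue)
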