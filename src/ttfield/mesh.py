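"""Tetrahedral volume meshes on rectilinear lattices.

The package meshes all phantoms on a tensor-product (rectilinear) grid whose
boxes are split into six tetrahedra with the Kuhn (Freudenthal) pattern.  The
same split is applied in every box, which makes the triangulation conforming
across box faces — including between regions of different grid spacing along
the same axis — so graded meshes (fine near a tumour, coarse elsewhere) need
no hanging-node treatment.

Coordinates are millimetres everywhere at this level; the FEM layer converts
to SI metres internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "TISSUES",
    "TISSUE_NAMES",
    "TetMesh",
    "graded_axis",
    "build_lattice_mesh",
    "validate_mesh",
]

# Canonical tissue label codes shared across the package.
TISSUES: dict[str, int] = {
    "skin": 1,
    "bone": 2,
    "csf": 3,
    "gm": 4,
    "wm": 5,
    "tumor_shell": 6,
    "tumor_core": 7,
}
TISSUE_NAMES: dict[int, str] = {v: k for k, v in TISSUES.items()}

# Local faces of a positively oriented tet, outward-oriented.
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]], dtype=np.int64)


@dataclass
class TetMesh:
    """Tetrahedral mesh with per-element tissue labels and boundary patches.

    Attributes
    ----------
    nodes : (n, 3) float array, node coordinates in mm.
    tets : (m, 4) int array, node indices; all elements positively oriented.
    tet_label : (m,) int array of tissue codes (see :data:`TISSUES`).
    label_names : mapping code -> tissue name; defaults to the shared registry
        and may be extended for custom labels.
    boundary_patches : named sets of oriented surface triangles (node triples),
        e.g. electrode disc footprints.
    metadata : free-form provenance (phantom parameters, seed, ...).
    """

    nodes: np.ndarray
    tets: np.ndarray
    tet_label: np.ndarray
    label_names: dict[int, str] = field(default_factory=lambda: dict(TISSUE_NAMES))
    boundary_patches: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.float64).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.tet_label = np.asarray(self.tet_label, dtype=np.int64).reshape(-1)
        if len(self.tet_label) != len(self.tets):
            raise ValueError("tet_label length does not match number of tets")
        self._volumes: np.ndarray | None = None
        self._centroids: np.ndarray | None = None
        self._boundary: np.ndarray | None = None

    # -- derived per-element quantities -------------------------------------

    def element_volumes(self) -> np.ndarray:
        """Signed volumes in mm^3 (positive for a valid mesh); cached."""
        if self._volumes is None:
            p = self.nodes[self.tets]
            d = p[:, 1:] - p[:, :1]
            self._volumes = np.linalg.det(d) / 6.0
        return self._volumes

    def centroids(self) -> np.ndarray:
        if self._centroids is None:
            self._centroids = self.nodes[self.tets].mean(axis=1)
        return self._centroids

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def label_volume(self, label: str | int) -> float:
        code = TISSUES.get(label, label) if isinstance(label, str) else label
        if isinstance(label, str) and label not in TISSUES:
            rev = {v: k for k, v in self.label_names.items()}
            if label not in rev:
                raise KeyError(f"unknown tissue label {label!r}")
            code = rev[label]
        return float(self.element_volumes()[self.tet_label == code].sum())

    def label_mask(self, labels: Iterable[str | int]) -> np.ndarray:
        codes = set()
        rev = {v: k for k, v in self.label_names.items()}
        for lab in labels:
            if isinstance(lab, str):
                if lab in rev:
                    codes.add(rev[lab])
                elif lab in TISSUES:
                    codes.add(TISSUES[lab])
                else:
                    raise KeyError(f"unknown tissue label {lab!r}")
            else:
                codes.add(int(lab))
        return np.isin(self.tet_label, sorted(codes))

    # -- boundary -----------------------------------------------------------

    def boundary_triangles(self) -> np.ndarray:
        """Oriented (outward) surface triangles: faces owned by a single tet."""
        if self._boundary is None:
            faces = self.tets[:, _TET_FACES].reshape(-1, 3)
            key = np.sort(faces, axis=1)
            _, idx, inv, counts = np.unique(
                key, axis=0, return_index=True, return_inverse=True, return_counts=True
            )
            single = counts[inv] == 1
            self._boundary = faces[single]
        return self._boundary

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_triangles())

    def copy(self) -> "TetMesh":
        return TetMesh(
            self.nodes.copy(),
            self.tets.copy(),
            self.tet_label.copy(),
            dict(self.label_names),
            {k: v.copy() for k, v in self.boundary_patches.items()},
            dict(self.metadata),
        )


def graded_axis(
    lo: float,
    hi: float,
    coarse: float,
    window: tuple[float, float] | None = None,
    fine: float | None = None,
    growth: float = 1.4,
) -> np.ndarray:
    """1-D grid coordinates from ``lo`` to ``hi``.

    Uniform spacing ``coarse`` by default.  If a ``window`` is given, spacing
    is ``fine`` inside it and grows geometrically (factor ``growth``) outside
    until it reaches ``coarse``; each outer segment is rescaled so the axis
    ends exactly on ``lo``/``hi``.
    """
    if hi <= lo:
        raise ValueError(f"empty axis range [{lo}, {hi}]")
    if window is None or fine is None:
        n = max(1, round((hi - lo) / coarse))
        return np.linspace(lo, hi, n + 1)
    wlo, whi = max(lo, window[0]), min(hi, window[1])
    if whi <= wlo:
        n = max(1, round((hi - lo) / coarse))
        return np.linspace(lo, hi, n + 1)

    nf = max(1, round((whi - wlo) / fine))
    inner = np.linspace(wlo, whi, nf + 1)

    def _outward(start: float, stop: float, sign: float) -> np.ndarray:
        # breakpoints marching from start toward stop; rescaled to end on stop
        pts = [start]
        step = fine
        while sign * (stop - pts[-1]) > 1e-12:
            step = min(step * growth, coarse)
            pts.append(pts[-1] + sign * step)
        pts = np.asarray(pts)
        if len(pts) > 1:
            pts = start + (pts - start) * (stop - start) / (pts[-1] - start)
        return pts

    right = _outward(whi, hi, +1.0)[1:]
    left = _outward(wlo, lo, -1.0)[1:][::-1]
    return np.concatenate([left, inner, right])


def _kuhn_patterns() -> np.ndarray:
    """Six tets per box as indices into the 8 box corners (binary (i,j,k)).

    Corner index = 4*i + 2*j + k.  Each tet follows one permutation of the
    axes from corner (0,0,0) to (1,1,1); odd permutations are swapped to keep
    positive orientation.
    """
    from itertools import permutations

    axes_step = np.array([4, 2, 1])  # corner-index increment per axis
    pats = []
    for perm in permutations(range(3)):
        c = [0]
        for ax in perm:
            c.append(c[-1] + axes_step[ax])
        # parity: sign of det of permuted unit vectors
        sign = 1
        p = list(perm)
        for i in range(3):
            for j in range(i + 1, 3):
                if p[i] > p[j]:
                    sign = -sign
        if sign < 0:
            c[1], c[2] = c[2], c[1]
        pats.append(c)
    return np.array(pats, dtype=np.int64)


_KUHN = _kuhn_patterns()


def _kuhn_variants() -> np.ndarray:
    """Reflected Kuhn patterns per octant, orientation-corrected.

    Variant m (bits: 4 = flip x, 2 = flip y, 1 = flip z) is the base pattern
    with the corresponding corner-index bits toggled.  Using the reflected
    pattern in cells on the negative side of each mirror plane makes the
    whole triangulation invariant under the mirrors; patterns meeting at a
    mid-plane share faces perpendicular to the flipped axis, whose diagonals
    are mirror-invariant, so the mesh stays conforming.
    """
    corner_xyz = np.array(
        [[(c >> 2) & 1, (c >> 1) & 1, c & 1] for c in range(8)], dtype=float
    )
    variants = np.empty((8, 6, 4), dtype=np.int64)
    for m in range(8):
        pat = _KUHN ^ m
        for t in range(6):
            p = corner_xyz[pat[t]]
            if np.linalg.det(p[1:] - p[0]) < 0:
                pat[t, [1, 2]] = pat[t, [2, 1]]
        variants[m] = pat
    return variants


_KUHN_VARIANTS = _kuhn_variants()


def build_lattice_mesh(
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    keep: "np.ndarray | None" = None,
    mirror_origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Mesh the box spanned by sorted coordinate arrays with 6 tets per cell.

    Cells on the negative side of each ``mirror_origin`` plane use the
    reflected split so that a phantom symmetric about those planes gets a
    mirror-symmetric triangulation (a slab meshed from 0 upward sits in one
    octant and is unaffected).

    Parameters
    ----------
    keep : optional boolean mask over tets (after the 6-way split), evaluated
        by the caller on tet centroids; unused nodes are compacted away.

    Returns
    -------
    (nodes, tets)
    """
    xs, ys, zs = (np.asarray(a, dtype=np.float64) for a in (xs, ys, zs))
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    if min(nx, ny, nz) < 1:
        raise ValueError("each axis needs at least one cell")
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(ix, iy, iz):
        return (ix * (ny + 1) + iy) * (nz + 1) + iz

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
    # 8 corner node ids per cell, corner index = 4*i + 2*j + k
    corners = np.empty((len(ix), 8), dtype=np.int64)
    for ci in range(8):
        i, j, k = (ci >> 2) & 1, (ci >> 1) & 1, ci & 1
        corners[:, ci] = nid(ix + i, iy + j, iz + k)
    cx = 0.5 * (xs[ix] + xs[ix + 1])
    cy = 0.5 * (ys[iy] + ys[iy + 1])
    cz = 0.5 * (zs[iz] + zs[iz + 1])
    octant = (
        4 * (cx < mirror_origin[0]).astype(np.int64)
        + 2 * (cy < mirror_origin[1])
        + (cz < mirror_origin[2])
    )
    tets = np.empty((len(ix), 6, 4), dtype=np.int64)
    for m in range(8):
        sel = octant == m
        if sel.any():
            tets[sel] = corners[sel][:, _KUHN_VARIANTS[m].reshape(-1)].reshape(-1, 6, 4)
    tets = tets.reshape(-1, 4)  # (ncells*6, 4)

    if keep is not None:
        tets = tets[keep]
    used = np.unique(tets)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return nodes[used], remap[tets]


def validate_mesh(mesh: TetMesh) -> None:
    """Raise if the mesh is structurally invalid.

    Checks positive orientation and that every interior face is shared by
    exactly two tets (faces shared by three or more indicate a broken
    topology).
    """
    vols = mesh.element_volumes()
    if not np.all(vols > 0):
        bad = int(np.argmin(vols))
        raise ValueError(f"non-positive tet volume at element {bad}: {vols[bad]:g} mm^3")
    faces = np.sort(mesh.tets[:, _TET_FACES].reshape(-1, 3), axis=1)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    if counts.max() > 2:
        raise ValueError("face shared by more than two tets")
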