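"""Electrode montages: coordinate frame and Optune-style 3x3 scalp arrays.

The montage frame follows the clinical convention: origin midway between
the ear landmarks, x to the right, y anterior, z completing a right-handed
frame.  Each transducer array is nine 20 mm discs in a 3x3 grid with
centre-to-centre pitches of 45 mm along the row axis and 22 mm along the
orthogonal in-plane axis, laid out in the local tangent plane and projected
onto the scalp (nearest-surface-point projection; disc footprints use the
Euclidean — not true geodesic — radius, an adequate approximation at scalp
curvature).  The two clinical pairs are left/right and anterior/posterior,
with the left and posterior arrays as current sources and a target peak
current of 0.9 A per active pair.

Electrically each array is an ideal Dirichlet electrode: all nine discs of
an array share one fixed potential, and the solve is rescaled to the target
current afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TetMesh

__all__ = [
    "CoordinateFrame",
    "ElectrodeArray",
    "Montage",
    "define_coordinate_system",
    "project_to_surface",
    "layout_array",
    "place_standard_montages",
]

DEFAULT_PITCH_MM = (45.0, 22.0)
DEFAULT_DISC_DIAMETER_MM = 20.0
DEFAULT_CURRENT_A = 0.9


@dataclass(frozen=True)
class CoordinateFrame:
    """Rigid transform into the montage frame: p' = R (p - origin)."""

    origin: np.ndarray  # (3,)
    R: np.ndarray  # (3, 3), rows are the frame axes in mesh coordinates

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.origin) @ self.R.T

    @property
    def x_axis(self) -> np.ndarray:
        return self.R[0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.R[1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.R[2]

    @staticmethod
    def identity() -> "CoordinateFrame":
        return CoordinateFrame(np.zeros(3), np.eye(3))


@dataclass
class ElectrodeArray:
    """Nine scalp discs sharing one electric potential."""

    array_id: str
    centers: np.ndarray  # (9, 3) disc centres on the scalp, mm
    disc_nodes: list  # 9 arrays of surface node indices, pairwise disjoint
    diameter_mm: float = DEFAULT_DISC_DIAMETER_MM

    def all_nodes(self) -> np.ndarray:
        return np.unique(np.concatenate(self.disc_nodes))

    def footprint_area_mm2(self, mesh: TetMesh) -> float:
        """Total area of boundary triangles fully inside the disc node sets."""
        tris = mesh.boundary_triangles()
        nodeset = np.zeros(len(mesh.nodes), dtype=bool)
        nodeset[self.all_nodes()] = True
        inside = nodeset[tris].all(axis=1)
        p = mesh.nodes[tris[inside]]
        return float(
            0.5 * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
            ).sum()
        )


@dataclass
class Montage:
    """A source and a sink array driven by one current source."""

    source: ElectrodeArray
    sink: ElectrodeArray
    current_A: float = DEFAULT_CURRENT_A
    name: str = ""

    def __post_init__(self) -> None:
        if self.source.array_id == self.sink.array_id:
            raise ValueError("source and sink arrays must differ")
        if not self.current_A > 0:
            raise ValueError("target current must be positive")
        if not self.name:
            self.name = f"{self.source.array_id}-{self.sink.array_id}"


def _surface_distance(mesh: TetMesh, point: np.ndarray) -> float:
    q, _ = project_to_surface(mesh, np.asarray(point, dtype=float)[None, :])
    return float(np.linalg.norm(q[0] - point))


def define_coordinate_system(
    mesh: TetMesh,
    left_ear: Sequence[float],
    right_ear: Sequence[float],
    forehead: Sequence[float],
    surface_tol_mm: float = 5.0,
) -> CoordinateFrame:
    """Build the montage frame from ear and forehead landmarks on the scalp.

    x runs from the left to the right ear landmark, y toward the forehead
    (orthogonalised), z = x cross y; the origin sits midway between the
    ears.  On the symmetric ellipsoid phantom with canonical landmarks this
    reduces to the identity transform.
    """
    le, re, fh = (np.asarray(p, dtype=float) for p in (left_ear, right_ear, forehead))
    origin = 0.5 * (le + re)
    xv = re - le
    yv = fh - origin
    cr = np.cross(xv, yv)
    if np.linalg.norm(cr) < 1e-9 * max(np.linalg.norm(xv) * np.linalg.norm(yv), 1e-30):
        raise ValueError("landmarks are collinear; cannot define a frame")
    for name, p in (("left_ear", le), ("right_ear", re), ("forehead", fh)):
        d = _surface_distance(mesh, p)
        if d > surface_tol_mm:
            raise ValueError(
                f"landmark {name} is {d:.1f} mm off the skin surface "
                f"(tolerance {surface_tol_mm} mm)"
            )
    x = xv / np.linalg.norm(xv)
    y = yv - (yv @ x) * x
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return CoordinateFrame(origin=origin, R=np.vstack([x, y, z]))


# ---------------------------------------------------------------------------
# surface projection
# ---------------------------------------------------------------------------

def _closest_point_on_triangle(p: np.ndarray, a, b, c) -> np.ndarray:
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d4 * d5
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
    denom = va + vb + vc
    return a + ab * (vb / denom) + ac * (vc / denom)


def project_to_surface(
    mesh: TetMesh, points: np.ndarray, k_candidates: int = 48
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest points on the boundary surface and their outward normals."""
    tris = mesh.boundary_triangles()
    tp = mesh.nodes[tris]
    centroids = tp.mean(axis=1)
    tree = cKDTree(centroids)
    normals = np.cross(tp[:, 1] - tp[:, 0], tp[:, 2] - tp[:, 0])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty_like(points)
    out_n = np.empty_like(points)
    k = min(k_candidates, len(tris))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    for i, p in enumerate(points):
        best, bestd, bestt = None, np.inf, -1
        for t in cand[i]:
            q = _closest_point_on_triangle(p, tp[t, 0], tp[t, 1], tp[t, 2])
            d = np.linalg.norm(q - p)
            if d < bestd:
                best, bestd, bestt = q, d, t
        out[i] = best
        out_n[i] = normals[bestt]
    return out, out_n


def _local_normal(mesh: TetMesh, point: np.ndarray, radius_mm: float = 15.0) -> np.ndarray:
    """Area-weighted outward normal of boundary triangles near a point."""
    tris = mesh.boundary_triangles()
    tp = mesh.nodes[tris]
    cent = tp.mean(axis=1)
    near = np.linalg.norm(cent - point, axis=1) < radius_mm
    if not near.any():
        near = slice(None)
    cr = np.cross(tp[near, 1] - tp[near, 0], tp[near, 2] - tp[near, 0])
    n = cr.sum(axis=0)
    n /= np.linalg.norm(n)
    # orient outward: away from the volume centroid
    vols = mesh.element_volumes()
    center = (mesh.centroids() * vols[:, None]).sum(axis=0) / vols.sum()
    if n @ (point - center) < 0:
        n = -n
    return n


def layout_array(
    mesh: TetMesh,
    center: Sequence[float],
    row_axis: Sequence[float],
    array_id: str,
    pitch_mm: tuple[float, float] = DEFAULT_PITCH_MM,
    disc_diameter_mm: float = DEFAULT_DISC_DIAMETER_MM,
    attach_patches: bool = True,
) -> ElectrodeArray:
    """Place a 3x3 disc array on the scalp around ``center``.

    The grid is laid out in the tangent plane at ``center`` — pitch
    ``pitch_mm[0]`` along ``row_axis`` (projected in-plane) and
    ``pitch_mm[1]`` along the orthogonal in-plane axis — and each grid point
    is projected to its nearest point on the scalp surface.  A disc's
    footprint is the set of surface nodes within one disc radius of its
    projected centre, each node assigned to its nearest disc centre so that
    footprints are pairwise disjoint.
    """
    center = np.asarray(center, dtype=float)
    csurf, _ = project_to_surface(mesh, center[None, :])
    center = csurf[0]
    n = _local_normal(mesh, center)
    u = np.asarray(row_axis, dtype=float)
    u = u - (u @ n) * n
    if np.linalg.norm(u) < 1e-9:
        raise ValueError("row_axis is parallel to the surface normal")
    u /= np.linalg.norm(u)
    v = np.cross(n, u)

    offsets = [(i, j) for j in (-1, 0, 1) for i in (-1, 0, 1)]
    grid = np.array(
        [center + i * pitch_mm[0] * u + j * pitch_mm[1] * v for i, j in offsets]
    )
    centers, _ = project_to_surface(mesh, grid)

    bnodes = mesh.boundary_nodes()
    bp = mesh.nodes[bnodes]
    radius = disc_diameter_mm / 2.0
    d2 = ((bp[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)  # (nb, 9)
    nearest = np.argmin(d2, axis=1)
    within = d2[np.arange(len(bp)), nearest] <= radius**2
    disc_nodes = []
    for k in range(9):
        sel = bnodes[within & (nearest == k)]
        if sel.size == 0:
            raise ValueError(
                f"disc {k} of array {array_id!r} has an empty footprint; "
                "use a finer surface mesh"
            )
        disc_nodes.append(sel)

    arr = ElectrodeArray(
        array_id=array_id,
        centers=centers,
        disc_nodes=disc_nodes,
        diameter_mm=disc_diameter_mm,
    )
    if attach_patches:
        tris = mesh.boundary_triangles()
        members = np.zeros(len(mesh.nodes), dtype=bool)
        members[arr.all_nodes()] = True
        mesh.boundary_patches[f"electrode_{array_id}"] = tris[members[tris].all(axis=1)]
    return arr


def _extreme_surface_point(mesh: TetMesh, direction: np.ndarray) -> np.ndarray:
    """Boundary node where the axis through the origin meets the scalp.

    Implemented as the boundary node nearest to a far point along the axis,
    which maximises the projection while breaking staircase ties in favour
    of on-axis nodes.
    """
    bn = mesh.boundary_nodes()
    p = mesh.nodes[bn]
    far = direction / np.linalg.norm(direction) * 4.0 * np.abs(mesh.nodes).max()
    return p[np.argmin(((p - far) ** 2).sum(axis=1))]


def place_standard_montages(
    mesh: TetMesh,
    frame: CoordinateFrame | None = None,
    pitch_mm: tuple[float, float] = DEFAULT_PITCH_MM,
    disc_diameter_mm: float = DEFAULT_DISC_DIAMETER_MM,
    current_A: float = DEFAULT_CURRENT_A,
) -> tuple[Montage, Montage]:
    """The two clinical pairs on a head mesh: (L/R montage, A/P montage).

    Left/right arrays are centred where the +-x axis of the montage frame
    meets the scalp (above the ear canals), anterior/posterior on the +-y
    intersections; the left and posterior arrays are the sources.  The
    45 mm pitch runs along the horizontal row direction (y for the lateral
    arrays, x for the frontal/occipital ones), 22 mm along z.
    """
    frame = frame or CoordinateFrame.identity()
    ex, ey, ez = frame.x_axis, frame.y_axis, frame.z_axis
    placements = {
        "left": (-ex, ey),
        "right": (ex, ey),
        "anterior": (ey, ex),
        "posterior": (-ey, ex),
    }
    arrays = {}
    for name, (axis, row) in placements.items():
        c = _extreme_surface_point(mesh, axis)
        arrays[name] = layout_array(
            mesh, c, row, name, pitch_mm=pitch_mm, disc_diameter_mm=disc_diameter_mm
        )

    ids = list(arrays)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            common = np.intersect1d(arrays[a].all_nodes(), arrays[b].all_nodes())
            if common.size:
                raise ValueError(
                    f"electrode arrays {a!r} and {b!r} overlap; the phantom is "
                    "too small for the requested array geometry"
                )
    m_lr = Montage(arrays["left"], arrays["right"], current_A, name="LR")
    m_ap = Montage(arrays["posterior"], arrays["anterior"], current_A, name="AP")
    return m_lr, m_ap
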