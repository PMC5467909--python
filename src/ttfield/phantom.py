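"""Synthetic head and slab phantoms with embedded spherical tumours.

The head is modelled as five strictly nested ellipsoidal compartments
(skin, bone, CSF, grey matter, white matter) whose outer semi-axes default
to 75 x 95 x 85 mm — i.e. roughly 150 mm left/right by 190 mm
anterior/posterior, the adult head extents the montage geometry assumes.
Layered slabs serve as validation phantoms with closed-form solutions, and
an optional CSF-filled slot in the slab emulates a sulcus for hot-spot
experiments.

Tumours are two-compartment spheres: an active shell (default outer
diameter 20 mm) around a necrotic core (default 14 mm), or solid shell
tissue throughout.  Elements are labelled by centroid membership; points
falling exactly on a compartment surface belong to the inner compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mesh import TISSUES, TetMesh, build_lattice_mesh, graded_axis

__all__ = [
    "TumorSpec",
    "FiberField",
    "CsfSlot",
    "DEFAULT_SEMI_AXES",
    "build_slab_phantom",
    "build_head_phantom",
    "embed_tumor",
    "synth_fiber_field",
]

# Outer semi-axes (mm) of each nested shell.  Outermost (skin) matches the
# 150/190 mm head extents; shell thicknesses skin 6, bone 7, CSF 3, GM 4 mm
# are representative adult values (not anatomical ground truth) and are
# overridable via the semi_axes argument / phantom config.
DEFAULT_SEMI_AXES: dict[str, tuple[float, float, float]] = {
    "skin": (75.0, 95.0, 85.0),
    "bone": (69.0, 89.0, 79.0),
    "csf": (62.0, 82.0, 72.0),
    "gm": (59.0, 79.0, 69.0),
    "wm": (55.0, 75.0, 65.0),
}

_SHELL_ORDER = ("skin", "bone", "csf", "gm", "wm")


@dataclass(frozen=True)
class TumorSpec:
    """Spherical two-compartment tumour in the montage coordinate frame."""

    center: tuple[float, float, float]
    outer_diameter: float = 20.0
    core_diameter: float = 14.0
    solid: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.core_diameter < self.outer_diameter):
            raise ValueError(
                f"need 0 < core_diameter < outer_diameter, got "
                f"{self.core_diameter} / {self.outer_diameter}"
            )

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2.0

    @property
    def core_radius(self) -> float:
        return self.core_diameter / 2.0


@dataclass
class FiberField:
    """Synthetic stand-in for diffusion-MRI tensors.

    ``tensors`` are symmetric positive definite with unit geometric-mean
    eigenvalue (arbitrary units — only eigenvector frames and eigenvalue
    ratios carry information); ``directions`` are the unit principal
    eigenvectors.
    """

    directions: np.ndarray  # (m, 3)
    tensors: np.ndarray  # (m, 3, 3)
    fa: float


@dataclass(frozen=True)
class CsfSlot:
    """Sulcus surrogate: a CSF-filled slot cut downward from the top plate."""

    x_range: tuple[float, float]
    depth: float
    y_range: tuple[float, float] | None = None
    label: str = "csf"


def build_slab_phantom(
    layers: Sequence[tuple[float, str]],
    lateral_size: float | tuple[float, float] = 20.0,
    resolution: float = 1.0,
    slot: CsfSlot | None = None,
) -> TetMesh:
    """Layered slab stacked along z with plate patches on the two z-faces.

    Parameters
    ----------
    layers : sequence of (thickness_mm, tissue_label), bottom to top.
    lateral_size : x/y extent in mm (scalar or (sx, sy)).
    slot : optional CSF-filled slot reaching down from the top plate.

    The two faces normal to the stacking axis are exposed as boundary
    patches ``plate_lo`` (z = 0) and ``plate_hi`` (z = total thickness).
    """
    if len(layers) == 0:
        raise ValueError("layers must not be empty")
    for i, (t, lab) in enumerate(layers):
        if t <= 0:
            raise ValueError(f"layer {i} ({lab!r}) has non-positive thickness {t}")
        if lab not in TISSUES:
            raise ValueError(f"layer {i} has unknown tissue label {lab!r}")
    sx, sy = (lateral_size, lateral_size) if np.isscalar(lateral_size) else lateral_size

    xs = graded_axis(0.0, sx, resolution)
    ys = graded_axis(0.0, sy, resolution)
    zparts, z0 = [], 0.0
    for t, _ in layers:
        n = max(1, round(t / resolution))
        zparts.append(np.linspace(z0, z0 + t, n + 1)[1 if zparts else 0 :])
        z0 += t
    zs = np.concatenate(zparts)

    nodes, tets = build_lattice_mesh(xs, ys, zs)
    mesh = TetMesh(nodes, tets, np.zeros(len(tets), dtype=np.int64))

    bounds = np.cumsum([t for t, _ in layers])
    codes = np.array([TISSUES[lab] for _, lab in layers])
    cz = mesh.centroids()[:, 2]
    mesh.tet_label = codes[np.searchsorted(bounds, cz)]

    if slot is not None:
        c = mesh.centroids()
        inside = (c[:, 0] > slot.x_range[0]) & (c[:, 0] < slot.x_range[1])
        if slot.y_range is not None:
            inside &= (c[:, 1] > slot.y_range[0]) & (c[:, 1] < slot.y_range[1])
        inside &= c[:, 2] > z0 - slot.depth
        mesh.tet_label = np.where(inside, TISSUES[slot.label], mesh.tet_label)

    tris = mesh.boundary_triangles()
    triz = mesh.nodes[tris][:, :, 2]
    tol = 1e-9 * max(sx, sy, z0)
    mesh.boundary_patches["plate_lo"] = tris[np.all(np.abs(triz - 0.0) < tol, axis=1)]
    mesh.boundary_patches["plate_hi"] = tris[np.all(np.abs(triz - z0) < tol, axis=1)]
    mesh.metadata.update(
        phantom="slab",
        layers=[(float(t), lab) for t, lab in layers],
        resolution_mm=float(resolution),
    )
    return mesh


def build_box_phantom(
    size: float | tuple[float, float, float],
    medium: str = "wm",
    resolution: float = 4.0,
    refine_center: tuple[float, float, float] | None = None,
    refine_radius: float = 14.0,
    fine_resolution: float | None = None,
) -> TetMesh:
    """Homogeneous box centred at the origin with plates on the z faces.

    Validation geometry for sphere-in-uniform-field cross-checks: driving
    the ``plate_lo``/``plate_hi`` patches with a potential difference
    ``E0 * Lz`` produces a uniform far field E0 along z.  Supports the same
    local grading as the head phantom so an embedded tumour shell can be
    resolved without refining the whole box.
    """
    if medium not in TISSUES:
        raise ValueError(f"unknown tissue label {medium!r}")
    sx, sy, sz = (size, size, size) if np.isscalar(size) else size
    coords = []
    for k, s in enumerate((sx, sy, sz)):
        window = None
        if refine_center is not None and fine_resolution is not None:
            window = (refine_center[k] - refine_radius, refine_center[k] + refine_radius)
        coords.append(graded_axis(-s / 2, s / 2, resolution, window, fine_resolution))
    nodes, tets = build_lattice_mesh(*coords)
    mesh = TetMesh(nodes, tets, np.full(len(tets), TISSUES[medium], dtype=np.int64))
    tris = mesh.boundary_triangles()
    triz = mesh.nodes[tris][:, :, 2]
    tol = 1e-9 * max(sx, sy, sz)
    mesh.boundary_patches["plate_lo"] = tris[np.all(np.abs(triz + sz / 2) < tol, axis=1)]
    mesh.boundary_patches["plate_hi"] = tris[np.all(np.abs(triz - sz / 2) < tol, axis=1)]
    mesh.metadata.update(phantom="box", size=(float(sx), float(sy), float(sz)),
                         resolution_mm=float(resolution))
    return mesh


def _inside(points: np.ndarray, semi_axes: Sequence[float]) -> np.ndarray:
    a = np.asarray(semi_axes, dtype=float)
    return ((points / a) ** 2).sum(axis=1) <= 1.0


def build_head_phantom(
    semi_axes: dict[str, tuple[float, float, float]] | None = None,
    resolution: float = 4.0,
    refine_center: tuple[float, float, float] | None = None,
    refine_radius: float = 14.0,
    fine_resolution: float | None = None,
) -> TetMesh:
    """Five-compartment nested-ellipsoid head phantom centred at the origin.

    ``refine_center``/``refine_radius``/``fine_resolution`` grade the lattice
    to a finer spacing inside a cubic window around a point of interest
    (typically the tumour), keeping the global node count tractable while
    resolving the 3 mm tumour shell.
    """
    axes = dict(DEFAULT_SEMI_AXES if semi_axes is None else semi_axes)
    missing = [s for s in _SHELL_ORDER if s not in axes]
    if missing:
        raise ValueError(f"semi_axes missing shells: {missing}")
    for outer, inner in zip(_SHELL_ORDER, _SHELL_ORDER[1:]):
        ao, ai = np.asarray(axes[outer]), np.asarray(axes[inner])
        if not np.all(ai < ao):
            raise ValueError(
                f"shells not strictly nested: {inner} {tuple(ai)} not inside "
                f"{outer} {tuple(ao)}"
            )

    a_skin = np.asarray(axes["skin"], dtype=float)
    coords = []
    for k in range(3):
        window = None
        if refine_center is not None and fine_resolution is not None:
            window = (refine_center[k] - refine_radius, refine_center[k] + refine_radius)
        coords.append(
            graded_axis(-a_skin[k], a_skin[k], resolution, window, fine_resolution)
        )
    xs, ys, zs = coords

    # first pass without filter to get centroids, then keep tets inside skin
    nodes, tets = build_lattice_mesh(xs, ys, zs)
    cent = nodes[tets].mean(axis=1)
    keep = _inside(cent, a_skin)
    nodes2, tets2 = build_lattice_mesh(xs, ys, zs, keep=keep)
    mesh = TetMesh(nodes2, tets2, np.zeros(len(tets2), dtype=np.int64))

    cent = mesh.centroids()
    label = np.full(len(tets2), TISSUES["skin"], dtype=np.int64)
    for shell in _SHELL_ORDER[1:]:
        label[_inside(cent, axes[shell])] = TISSUES[shell]
    mesh.tet_label = label
    mesh.metadata.update(
        phantom="head_ellipsoid",
        semi_axes={k: tuple(map(float, v)) for k, v in axes.items()},
        resolution_mm=float(resolution),
        fine_resolution_mm=None if fine_resolution is None else float(fine_resolution),
        refine_center=None if refine_center is None else tuple(map(float, refine_center)),
        seed=0,
    )
    return mesh


def embed_tumor(
    mesh: TetMesh,
    spec: TumorSpec,
    allowed_labels: Sequence[str] = ("gm", "wm"),
) -> TetMesh:
    """Relabel elements inside the tumour sphere(s); returns a new mesh.

    Every element whose centroid lies within the outer sphere must already
    carry an allowed brain label (or a tumour label, making re-embedding a
    no-op), otherwise the tumour would cross the dural/CSF boundary and the
    placement is rejected.  On head phantoms the geometric rule is applied
    as well: the tumour centre must lie inside the grey-matter ellipsoid
    shrunk by the outer radius, a resolution-independent containment test.
    """
    out = mesh.copy()
    semi = mesh.metadata.get("semi_axes")
    if semi and "gm" in semi:
        shrunk = np.asarray(semi["gm"], dtype=float) - spec.outer_radius
        c = np.asarray(spec.center, dtype=float)
        if np.any(shrunk <= 0) or ((c / shrunk) ** 2).sum() > 1.0:
            raise ValueError(
                f"tumour at {spec.center} would cross the dural/CSF boundary "
                f"(grey-matter semi-axes {tuple(semi['gm'])}, radius "
                f"{spec.outer_radius} mm)"
            )
    c = out.centroids() - np.asarray(spec.center, dtype=float)
    r2 = (c**2).sum(axis=1)
    in_outer = r2 <= spec.outer_radius**2
    ok_codes = {TISSUES[lab] for lab in allowed_labels}
    ok_codes |= {TISSUES["tumor_shell"], TISSUES["tumor_core"]}
    offending = np.unique(out.tet_label[in_outer & ~np.isin(out.tet_label, list(ok_codes))])
    if offending.size:
        names = [out.label_names.get(int(k), str(int(k))) for k in offending]
        raise ValueError(
            f"tumour at {spec.center} extends into {names}; placement must keep "
            "the entire tumour volume inside the brain (within the dural boundary)"
        )
    if not in_outer.any():
        raise ValueError(f"tumour at {spec.center} contains no mesh elements")
    label = out.tet_label.copy()
    label[in_outer] = TISSUES["tumor_shell"]
    if not spec.solid:
        label[r2 <= spec.core_radius**2] = TISSUES["tumor_core"]
    out.tet_label = label
    out.metadata["tumor"] = dict(
        center=tuple(map(float, spec.center)),
        outer_diameter_mm=float(spec.outer_diameter),
        core_diameter_mm=float(spec.core_diameter),
        solid=bool(spec.solid),
    )
    return out


def _prolate_major(fa: float) -> float:
    """Major/minor eigenvalue ratio of a prolate tensor with the given FA."""
    if fa == 0.0:
        return 1.0
    f2 = fa * fa
    return (1.0 + np.sqrt(1.0 - (1.0 - f2) * (1.0 - 2.0 * f2))) / (1.0 - f2)


def synth_fiber_field(
    mesh: TetMesh,
    pattern: str = "uniform",
    fa: float = 0.0,
    direction: Sequence[float] | None = None,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> FiberField:
    """Per-element prolate diffusion-like tensors with prescribed FA.

    Patterns
    --------
    ``uniform``
        every principal eigenvector equals ``direction`` (required).
    ``radial``
        principal eigenvector points away from ``center``.
    ``tangential_shells``
        azimuthal orientation (z-hat x r-hat), emulating fibre bundles
        wrapping around concentric shells.

    Tensors are prolate (two equal minor eigenvalues) and normalised to unit
    geometric-mean eigenvalue.
    """
    if not 0.0 <= fa < 1.0:
        raise ValueError(f"fractional anisotropy must be in [0, 1), got {fa}")
    cent = mesh.centroids()
    m = len(cent)
    if pattern == "uniform":
        if direction is None:
            raise ValueError("pattern 'uniform' requires a direction")
        d = np.asarray(direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        dirs = np.tile(d / n, (m, 1))
    elif pattern in ("radial", "tangential_shells"):
        r = cent - np.asarray(center, dtype=float)
        if pattern == "tangential_shells":
            r = np.cross(np.array([0.0, 0.0, 1.0]), r)
        nrm = np.linalg.norm(r, axis=1, keepdims=True)
        dirs = np.divide(r, nrm, out=np.tile([1.0, 0.0, 0.0], (m, 1)), where=nrm > 1e-12)
    else:
        raise ValueError(f"unknown fiber pattern {pattern!r}")

    major = _prolate_major(fa)
    scale = major ** (-1.0 / 3.0)  # geometric mean of (major, 1, 1) -> 1
    lam_major, lam_minor = major * scale, scale
    eye = np.eye(3)
    ddT = np.einsum("mi,mj->mij", dirs, dirs)
    tensors = lam_minor * (eye[None, :, :] - ddT) + lam_major * ddT
    return FiberField(directions=dirs, tensors=tensors, fa=float(fa))
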