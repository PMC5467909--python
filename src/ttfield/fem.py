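"""Electrostatic P1 finite-element solver for the volume-conduction problem.

Solves the quasi-static Laplace equation div(sigma grad V) = 0 on a
tetrahedral mesh with per-element conductivity tensors and Dirichlet
(fixed-potential) electrodes, the standard forward model for currents
injected through scalp electrodes.  First-order elements give a constant
field E = -grad V and current density J = sigma E per tetrahedron; electrode
currents are recovered as discrete boundary fluxes (residuals of the
unconstrained equations at electrode nodes, which is exact for the discrete
system), and the whole linear solution is rescaled so the prescribed peak
current flows through the source array.

All arithmetic is in SI units (m, V, S/m, A); mesh coordinates in mm are
converted on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, TYPE_CHECKING

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .conductivity import ConductivityField
from .mesh import TetMesh

if TYPE_CHECKING:  # pragma: no cover
    from .montage import ElectrodeArray, Montage

__all__ = [
    "FemSystem",
    "Solution",
    "assemble_system",
    "solve_potential",
    "element_field",
    "current_density",
    "electrode_current",
    "rescale_to_target",
    "solve_montage",
]

MM_TO_M = 1e-3
DEGENERATE_VOLUME_M3 = 1e-18  # ~1e-9 mm^3


def _shape_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element P1 shape-function gradients (1/m) and volumes (m^3)."""
    p = mesh.nodes[mesh.tets] * MM_TO_M  # (m, 4, 3)
    edges = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))  # columns p_i - p_0
    vol = np.linalg.det(edges) / 6.0
    if vol.size and vol.min() <= DEGENERATE_VOLUME_M3:
        bad = int(np.argmin(vol))
        raise ValueError(
            f"degenerate element {bad}: volume {vol[bad]:g} m^3 (non-positive "
            "or below resolution)"
        )
    ginv = np.linalg.inv(edges)  # rows are grad(lambda_1..3)
    grads = np.empty((len(vol), 4, 3))
    grads[:, 1:, :] = ginv
    grads[:, 0, :] = -ginv.sum(axis=1)
    return grads, vol


@dataclass
class FemSystem:
    """Assembled stiffness matrix plus cached element geometry.

    ``A`` is the full (no boundary conditions) symmetric positive
    semidefinite stiffness matrix in siemens; ``A @ V`` therefore yields
    nodal currents in amperes.
    """

    mesh: TetMesh
    A: sp.csr_matrix
    grads: np.ndarray  # (m, 4, 3), 1/m
    volumes_m3: np.ndarray  # (m,)


@dataclass
class Solution:
    """Node potentials and derived element fields for one montage solve."""

    V: np.ndarray  # (n,) volts
    E: np.ndarray  # (m, 3) V/m
    J: np.ndarray  # (m, 3) A/m^2
    scale: float = 1.0  # rescale factor already applied
    montage: str = ""
    source_current_A: float = np.nan
    sink_current_A: float = np.nan

    def norm_E(self) -> np.ndarray:
        return np.linalg.norm(self.E, axis=1)


def assemble_system(mesh: TetMesh, field: ConductivityField) -> FemSystem:
    """Assemble the P1 stiffness matrix for tensor conductivity.

    Element contribution K_ij = vol * grad(phi_i) . sigma grad(phi_j); rows
    of the assembled matrix sum to zero (constants are in the null space)
    until Dirichlet conditions are applied.
    """
    if len(field.tensors) != len(mesh.tets):
        raise ValueError("conductivity field does not match mesh element count")
    grads, vol = _shape_gradients(mesh)
    Ke = np.einsum("mid,mde,mje->mij", grads, field.tensors, grads)
    Ke *= vol[:, None, None]
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    n = len(mesh.nodes)
    A = sp.coo_matrix((Ke.reshape(-1), (rows, cols)), shape=(n, n)).tocsr()
    return FemSystem(mesh=mesh, A=A, grads=grads, volumes_m3=vol)


def _dirichlet_arrays(dirichlet) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dirichlet, Mapping):
        idx = np.fromiter(dirichlet.keys(), dtype=np.int64)
        vals = np.fromiter((dirichlet[i] for i in idx), dtype=np.float64)
    else:
        idx, vals = dirichlet
        idx = np.asarray(idx, dtype=np.int64)
        vals = np.asarray(vals, dtype=np.float64)
    if idx.size == 0 or np.unique(vals).size < 2:
        raise ValueError("need Dirichlet nodes with at least two distinct potentials")
    return idx, vals


def solve_potential(
    system: FemSystem,
    dirichlet,
    tol: float = 1e-9,
    method: str = "cg",
    maxiter: int | None = None,
) -> np.ndarray:
    """Solve for node potentials with fixed-potential electrode nodes.

    ``dirichlet`` is a node->potential mapping or an ``(indices, values)``
    pair.  ``method`` is ``'cg'`` (Jacobi-preconditioned conjugate
    gradients, the default) or ``'direct'`` (sparse LU).  In every case the
    relative residual of the reduced system is verified to be below ``tol``
    and the Dirichlet values are exact.
    """
    idx, vals = _dirichlet_arrays(dirichlet)
    n = system.A.shape[0]
    free = np.ones(n, dtype=bool)
    free[idx] = False
    fidx = np.nonzero(free)[0]
    Aff = system.A[fidx][:, fidx].tocsr()
    b = -system.A[fidx][:, idx] @ vals
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        raise ValueError("Dirichlet data produce a zero right-hand side")

    if method == "direct":
        lu = spla.splu(Aff.tocsc())
        x = lu.solve(b)
    elif method == "cg":
        M = sp.diags(1.0 / Aff.diagonal())
        maxiter = maxiter or 20 * int(np.sqrt(Aff.shape[0])) + 1000
        x, info = spla.cg(Aff, b, rtol=tol * 0.1, atol=0.0, M=M, maxiter=maxiter)
        if info > 0:
            res = np.linalg.norm(Aff @ x - b) / bnorm
            raise RuntimeError(
                f"CG did not converge in {maxiter} iterations "
                f"(relative residual {res:.3e} > {tol:g})"
            )
    else:
        raise ValueError(f"unknown solve method {method!r}")

    res = np.linalg.norm(Aff @ x - b) / bnorm
    if res > tol:
        raise RuntimeError(f"solver residual {res:.3e} exceeds tolerance {tol:g}")
    V = np.empty(n)
    V[fidx] = x
    V[idx] = vals
    return V


def element_field(mesh: TetMesh | FemSystem, V: np.ndarray) -> np.ndarray:
    """E = -grad V, constant per element, in V/m."""
    if isinstance(mesh, FemSystem):
        grads, tets = mesh.grads, mesh.mesh.tets
    else:
        grads, _ = _shape_gradients(mesh)
        tets = mesh.tets
    return -np.einsum("mi,mid->md", V[tets], grads)


def current_density(E: np.ndarray, field: ConductivityField) -> np.ndarray:
    """Ohm's law per element: J = sigma E, in A/m^2."""
    return np.einsum("mde,me->md", field.tensors, E)


def electrode_current(V: np.ndarray, array, system: FemSystem) -> float:
    """Net current (A) flowing from an electrode array into the volume.

    Computed as the sum over the array's Dirichlet nodes of the residuals of
    the unconstrained equations, which is the discretely exact boundary
    flux.  ``array`` may be an ElectrodeArray or a plain node-index array.
    """
    nodes = array.all_nodes() if hasattr(array, "all_nodes") else np.asarray(array)
    r = system.A @ V
    return float(r[nodes].sum())


def rescale_to_target(
    solution: Solution, target_A: float, system: FemSystem | None = None
) -> Solution:
    """Linearly rescale V, E, J so the source current equals ``target_A``."""
    if not target_A > 0:
        raise ValueError("target current must be positive")
    if not np.isfinite(solution.source_current_A) or solution.source_current_A == 0:
        raise ValueError("solution has no measured source current to rescale")
    f = target_A / solution.source_current_A
    return replace(
        solution,
        V=solution.V * f,
        E=solution.E * f,
        J=solution.J * f,
        scale=solution.scale * f,
        source_current_A=solution.source_current_A * f,
        sink_current_A=solution.sink_current_A * f,
    )


def solve_plates(
    mesh: TetMesh,
    field: ConductivityField,
    delta_V: float = 1.0,
    tol: float = 1e-9,
    method: str = "cg",
    system: FemSystem | None = None,
) -> Solution:
    """Drive a slab/box phantom's plate patches with a potential difference.

    ``plate_lo`` is held at +delta_V/2 and ``plate_hi`` at -delta_V/2 (so a
    stack along z sees a field pointing toward +z).  No current rescaling is
    applied; the measured plate currents are recorded on the solution.
    """
    for patch in ("plate_lo", "plate_hi"):
        if patch not in mesh.boundary_patches:
            raise ValueError(f"mesh has no {patch!r} boundary patch")
    if system is None:
        system = assemble_system(mesh, field)
    lo = np.unique(mesh.boundary_patches["plate_lo"])
    hi = np.unique(mesh.boundary_patches["plate_hi"])
    idx = np.concatenate([lo, hi])
    vals = np.concatenate([np.full(len(lo), delta_V / 2), np.full(len(hi), -delta_V / 2)])
    V = solve_potential(system, (idx, vals), tol=tol, method=method)
    E = element_field(system, V)
    return Solution(
        V=V,
        E=E,
        J=current_density(E, field),
        montage="plates",
        source_current_A=electrode_current(V, lo, system),
        sink_current_A=electrode_current(V, hi, system),
    )


def uniform_field_drive(
    mesh: TetMesh,
    field: ConductivityField,
    E0: float = 100.0,
    tol: float = 1e-9,
    method: str = "cg",
    system: FemSystem | None = None,
) -> Solution:
    """Plate drive sized to produce a nominal far field of E0 V/m along z."""
    z = mesh.nodes[:, 2]
    return solve_plates(
        mesh, field, delta_V=E0 * (z.max() - z.min()) * MM_TO_M,
        tol=tol, method=method, system=system,
    )


def solve_montage(
    mesh: TetMesh,
    field: ConductivityField,
    montage: "Montage",
    tol: float = 1e-9,
    method: str = "cg",
    system: FemSystem | None = None,
    rescale: bool = True,
) -> Solution:
    """End-to-end solve for one montage: +-0.5 V on the arrays, then rescale.

    The electrode potentials before rescaling are arbitrary; the final
    solution carries the montage's target peak current through the source
    array.  Pass a pre-assembled ``system`` to reuse the stiffness matrix
    across montages on the same mesh/conductivity.
    """
    if system is None:
        system = assemble_system(mesh, field)
    src = montage.source.all_nodes()
    snk = montage.sink.all_nodes()
    idx = np.concatenate([src, snk])
    vals = np.concatenate([np.full(len(src), 0.5), np.full(len(snk), -0.5)])
    V = solve_potential(system, (idx, vals), tol=tol, method=method)
    E = element_field(system, V)
    J = current_density(E, field)
    sol = Solution(
        V=V,
        E=E,
        J=J,
        montage=montage.name,
        source_current_A=electrode_current(V, src, system),
        sink_current_A=electrode_current(V, snk, system),
    )
    if rescale:
        sol = rescale_to_target(sol, montage.current_A)
    return sol
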