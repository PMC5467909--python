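"""Tissue conductivity models: isotropic table, direct-mapped tensors, MC.

Isotropic defaults (S/m): skin 0.465, bone 0.010, CSF 1.654, tumour shell
0.24, necrotic core 1.00 — in-vivo/in-vitro literature values at TTFields
frequencies.  Grey/white matter scalar references (0.275 / 0.126 S/m) are
literature-typical stand-ins and should be reviewed for any quantitative
application; they are deliberately front-and-centre in the config.

Anisotropy enters through *direct mapping*: the conductivity tensor of a
GM/WM element shares the eigenvector frame of the local diffusion-like
tensor, with eigenvalues rescaled so that (by default) their geometric mean
equals the tissue's scalar reference — the volume-normalised variant, which
keeps the effective tissue conductivity consistent with the isotropic
table.  An unnormalised variant (global scaling of the diffusion
eigenvalues) is available behind a flag.  The *mean conductivity* (MC)
surrogate replaces each tensor by the arithmetic mean of its eigenvalues
times the identity, isolating the effect of anisotropy in comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .mesh import TISSUES, TetMesh
from .phantom import FiberField

__all__ = [
    "DEFAULT_TISSUE_TABLE",
    "TissueTable",
    "ConductivityField",
    "assign_isotropic",
    "direct_map_tensors",
    "mean_conductivity",
]

EIGENVALUE_FLOOR = 1e-6  # S/m; keeps the FEM system positive definite

DEFAULT_TISSUE_TABLE: dict[str, float] = {
    "skin": 0.465,
    "bone": 0.010,
    "csf": 1.654,
    "gm": 0.275,
    "wm": 0.126,
    "tumor_shell": 0.24,
    "tumor_core": 1.00,
}


@dataclass(frozen=True)
class TissueTable:
    """Tissue label -> isotropic conductivity in S/m."""

    values: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_TABLE))

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.values.items() if not v > 0}
        if bad:
            raise ValueError(f"conductivities must be > 0, got {bad}")

    def __getitem__(self, label: str) -> float:
        return self.values[label]

    def sigma_of_code(self, code: int, label_names: Mapping[int, str]) -> float:
        name = label_names.get(int(code))
        if name is None or name not in self.values:
            raise KeyError(
                f"tissue label {name or code!r} has no conductivity in the table"
            )
        return self.values[name]


@dataclass
class ConductivityField:
    """Per-element symmetric 3x3 conductivity tensors (S/m)."""

    tensors: np.ndarray  # (m, 3, 3)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=np.float64)
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
            raise ValueError("tensors must have shape (m, 3, 3)")

    def check_spd(self, atol: float = 1e-12) -> None:
        sym_err = np.abs(self.tensors - np.transpose(self.tensors, (0, 2, 1))).max()
        if sym_err > 1e-10:
            raise ValueError(f"tensors not symmetric (max asymmetry {sym_err:g})")
        w = np.linalg.eigvalsh(self.tensors)
        if w.min() <= atol:
            idx = int(np.argmin(w.min(axis=1)))
            raise ValueError(f"non-SPD conductivity tensor at element {idx}")


def assign_isotropic(mesh: TetMesh, table: TissueTable | None = None) -> ConductivityField:
    """sigma * I per element from the tissue table."""
    table = table or TissueTable()
    codes = np.unique(mesh.tet_label)
    sigma_by_code = {int(c): table.sigma_of_code(c, mesh.label_names) for c in codes}
    sig = np.empty(len(mesh.tets))
    for c, s in sigma_by_code.items():
        sig[mesh.tet_label == c] = s
    tensors = sig[:, None, None] * np.eye(3)[None, :, :]
    return ConductivityField(tensors)


def direct_map_tensors(
    fibers: FiberField,
    mesh: TetMesh,
    table: TissueTable | None = None,
    normalize: str = "volume",
) -> ConductivityField:
    """Map diffusion-like tensors to conductivity tensors in GM/WM.

    Eigenvectors are inherited from the diffusion tensor.  With
    ``normalize='volume'`` (default) each element's conductivity eigenvalues
    are scaled so their geometric mean equals the tissue's scalar reference;
    with ``normalize='none'`` the diffusion eigenvalues are used directly up
    to the tissue reference as a global factor (geometric mean preserved only
    on average).  Non-brain tissues fall back to the isotropic table.
    """
    table = table or TissueTable()
    if normalize not in ("volume", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    out = assign_isotropic(mesh, table)
    brain = mesh.label_mask(["gm", "wm"])
    idx = np.nonzero(brain)[0]
    if idx.size == 0:
        return out

    D = np.asarray(fibers.tensors[idx], dtype=np.float64)
    w, v = np.linalg.eigh(D)  # ascending eigenvalues, orthonormal frames
    w = np.maximum(w, EIGENVALUE_FLOOR)
    if not np.all(w > 0):
        bad = int(idx[np.argmin(w.min(axis=1))])
        raise ValueError(f"non-SPD diffusion tensor at element {bad}")

    sigma_ref = np.where(
        mesh.tet_label[idx] == TISSUES["wm"], table["wm"], table["gm"]
    )
    gmean = np.exp(np.log(w).mean(axis=1))
    if normalize == "volume":
        lam = w * (sigma_ref / gmean)[:, None]
    else:
        lam = w * (sigma_ref / np.exp(np.log(gmean).mean()))[:, None]
    lam = np.maximum(lam, EIGENVALUE_FLOOR)
    out.tensors[idx] = np.einsum("mik,mk,mjk->mij", v, lam, v)
    return out


def mean_conductivity(fld: ConductivityField) -> ConductivityField:
    """Arithmetic-mean isotropisation: each tensor -> (tr sigma / 3) * I."""
    T = fld.tensors
    tr = np.trace(T, axis1=1, axis2=2) / 3.0
    # exactly-isotropic tensors pass through bit-identically
    iso = (
        (T[:, 0, 0] == T[:, 1, 1])
        & (T[:, 1, 1] == T[:, 2, 2])
        & (T[:, 0, 1] == 0) & (T[:, 0, 2] == 0) & (T[:, 1, 2] == 0)
        & (T[:, 1, 0] == 0) & (T[:, 2, 0] == 0) & (T[:, 2, 1] == 0)
    )
    tr = np.where(iso, T[:, 0, 0], tr)
    return ConductivityField(tr[:, None, None] * np.eye(3)[None, :, :])
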