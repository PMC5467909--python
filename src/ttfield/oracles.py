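"""Closed-form reference solutions for validating the FEM pipeline.

Three classical electrostatics results: the series (layered) slab, the
Maxwell sphere in a uniform applied field, and the coated (shelled) sphere
reduced to an equivalent homogeneous conductivity.  These quantify, in
analytically tractable geometry, the conductivity-contrast mechanism that
shapes treatment-field dose: a well-conducting inclusion draws current and
depresses its own interior field while boosting the field at its poles.

The sphere formulas assume an infinite external medium; FEM cross-checks
must use a computational domain at least five sphere diameters wide so the
residual boundary interaction stays well below the comparison tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OracleResult",
    "slab_series_field",
    "sphere_in_uniform_field",
    "shelled_sphere_in_uniform_field",
]


@dataclass(frozen=True)
class OracleResult:
    """Per-region reference values from a closed-form solution."""

    fields_Vpm: dict[str, float] = field(default_factory=dict)
    current_density_Apm2: float = np.nan
    current_A: float = np.nan
    sigma_equivalent_Spm: float = np.nan


def slab_series_field(
    layers: Sequence[tuple[float, float]],
    delta_V: float,
    area_mm2: float | None = None,
) -> OracleResult:
    """Series-resistor solution for a stack of conductive layers.

    Parameters
    ----------
    layers : sequence of (thickness_mm, sigma_Spm).
    delta_V : potential difference across the stack in volts.
    area_mm2 : optional plate area; if given the total current is reported.

    The normal current density J = delta_V / sum(d_i / sigma_i) is the same
    in every layer (continuity); the field in layer i is E_i = J / sigma_i.
    """
    if len(layers) == 0:
        raise ValueError("layers must not be empty")
    d = np.array([t for t, _ in layers], dtype=float) * 1e-3  # m
    s = np.array([sg for _, sg in layers], dtype=float)
    if np.any(d <= 0) or np.any(s <= 0):
        raise ValueError("thicknesses and conductivities must be positive")
    J = delta_V / float((d / s).sum())  # A/m^2
    fields = {f"layer{i}": float(J / s[i]) for i in range(len(layers))}
    I = np.nan if area_mm2 is None else float(J * area_mm2 * 1e-6)
    return OracleResult(fields_Vpm=fields, current_density_Apm2=float(J), current_A=I)


def sphere_in_uniform_field(sigma_i: float, sigma_e: float, E0: float) -> float:
    """Uniform interior field of a homogeneous sphere in an applied field E0.

    E_in = 3 sigma_e / (sigma_i + 2 sigma_e) * E0 — independent of sphere
    radius; a better-conducting inclusion (sigma_i > sigma_e) sees a reduced
    interior field.
    """
    if sigma_i <= 0 or sigma_e <= 0:
        raise ValueError("conductivities must be positive")
    return 3.0 * sigma_e / (sigma_i + 2.0 * sigma_e) * E0


def shelled_sphere_in_uniform_field(
    sigma_core: float,
    sigma_shell: float,
    sigma_ext: float,
    r_core: float,
    r_outer: float,
    E0: float,
) -> OracleResult:
    """Coated sphere in a uniform field via the equivalent-conductivity route.

    The core+shell composite behaves, seen from outside, exactly like a
    homogeneous sphere of conductivity

        sigma_eq = sigma_shell * [s_c + 2 s_s + 2 v (s_c - s_s)]
                               / [s_c + 2 s_s -   v (s_c - s_s)],
        v = (r_core / r_outer)^3,

    (the Maxwell-Garnett mixing rule).  The reported ``interior`` field is
    the uniform field of that equivalent sphere, which also equals the exact
    volume average of E over the whole composite; the ``core`` field is the
    exact uniform core field of the coated sphere,

        E_core = 9 sigma_s sigma_e E0
                 / [(s_c + 2 s_s)(s_s + 2 s_e) + 2 v (s_c - s_s)(s_s - s_e)],

    which reduces to two nested homogeneous-sphere transmissions as v -> 0.
    """
    if not 0 < r_core < r_outer:
        raise ValueError("need 0 < r_core < r_outer")
    if min(sigma_core, sigma_shell, sigma_ext) <= 0:
        raise ValueError("conductivities must be positive")
    v = (r_core / r_outer) ** 3
    num = sigma_core + 2 * sigma_shell + 2 * v * (sigma_core - sigma_shell)
    den = sigma_core + 2 * sigma_shell - v * (sigma_core - sigma_shell)
    sigma_eq = sigma_shell * num / den
    E_interior = sphere_in_uniform_field(sigma_eq, sigma_ext, E0)
    E_core = (
        9.0 * sigma_shell * sigma_ext * E0
        / (
            (sigma_core + 2 * sigma_shell) * (sigma_shell + 2 * sigma_ext)
            + 2 * v * (sigma_core - sigma_shell) * (sigma_shell - sigma_ext)
        )
    )
    return OracleResult(
        fields_Vpm={"interior": float(E_interior), "core": float(E_core)},
        sigma_equivalent_Spm=float(sigma_eq),
    )
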