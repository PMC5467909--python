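"""Dose metrics: volume-weighted field statistics, comparisons, hot spots.

Treatment-field dose in a region of interest is summarised by the median of
the field strength |E| over the region and by the interquartile range (IQR)
as the measure of field (non-)uniformity: a low IQR means the tissue sees a
uniform field, a high IQR means strong local variability.

Statistics are volume-weighted by default: each element contributes its
|E| with weight equal to its volume.  Quantiles use the cumulative-volume
convention in which a quantile falling strictly inside an element's volume
span takes that element's value, and a quantile landing exactly on the
boundary between two elements takes their midpoint — with equal volumes
this reduces to the ordinary sample median.  Unweighted statistics are
available via ``volume_weighted=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fem import Solution
from .mesh import TetMesh

__all__ = [
    "DoseStats",
    "FieldDifference",
    "weighted_quantile",
    "roi_statistics",
    "pairwise_fraction_ge",
    "difference_map",
    "hotspot_extract",
]


@dataclass(frozen=True)
class DoseStats:
    """Volume-weighted summary of |E| in a region of interest."""

    roi: tuple[str, ...]
    median_Vpm: float
    q1_Vpm: float
    q3_Vpm: float
    n_elements: int
    volume_mm3: float

    @property
    def iqr_Vpm(self) -> float:
        return self.q3_Vpm - self.q1_Vpm


@dataclass
class FieldDifference:
    """Signed per-element difference of field strengths on a shared mesh."""

    delta_normE: np.ndarray  # (m,) V/m, |E_A| - |E_B|
    median_delta_Vpm: float  # volume-weighted over the ROI


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Quantile of ``values`` under weights, boundary-midpoint convention.

    With cumulative weight fractions c_0=0 < c_1 < ... < c_n = 1 over the
    sorted values, the quantile at fraction q returns value_i when
    c_{i-1} < q < c_i, and (value_i + value_{i+1})/2 when q coincides with
    an interior boundary c_i.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("quantile fraction must be in [0, 1]")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty value set")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    total = cw[-1]
    if total <= 0:
        raise ValueError("weights must have positive sum")
    c = cw / total
    if q <= 0:
        return float(v[0])
    if q >= 1:
        return float(v[-1])
    i = int(np.searchsorted(c, q, side="left"))
    if i < len(v) - 1 and abs(c[i] - q) <= 1e-12:
        return float(0.5 * (v[i] + v[i + 1]))
    return float(v[min(i, len(v) - 1)])


def _roi_mask(mesh: TetMesh, roi_labels: Iterable[str] | None) -> np.ndarray:
    if roi_labels is None:
        return np.ones(len(mesh.tets), dtype=bool)
    labels = tuple(roi_labels)
    mask = mesh.label_mask(labels)
    if not mask.any():
        raise ValueError(f"ROI {labels} matches no elements")
    return mask


def roi_statistics(
    solution: Solution,
    mesh: TetMesh,
    roi_labels: Iterable[str] | None = None,
    volume_weighted: bool = True,
) -> DoseStats:
    """Median / Q1 / Q3 / IQR of |E| over the elements of an ROI."""
    labels = tuple(roi_labels) if roi_labels is not None else ("all",)
    mask = _roi_mask(mesh, roi_labels)
    normE = solution.norm_E()[mask]
    vol = mesh.element_volumes()[mask]
    if volume_weighted:
        q1, q2, q3 = (weighted_quantile(normE, vol, q) for q in (0.25, 0.5, 0.75))
    else:
        # sample statistics over elements (linear interpolation, numpy style)
        q1, q2, q3 = np.quantile(normE, [0.25, 0.5, 0.75])
    return DoseStats(
        roi=labels,
        median_Vpm=q2,
        q1_Vpm=q1,
        q3_Vpm=q3,
        n_elements=int(mask.sum()),
        volume_mm3=float(vol.sum()),
    )


def pairwise_fraction_ge(
    sol_a: Solution,
    sol_b: Solution,
    mesh: TetMesh,
    roi_labels: Iterable[str] | None = None,
) -> float:
    """Volume fraction of the ROI where |E_A| >= |E_B| (ties count as >=)."""
    mask = _roi_mask(mesh, roi_labels)
    vol = mesh.element_volumes()[mask]
    ge = sol_a.norm_E()[mask] >= sol_b.norm_E()[mask]
    return float(vol[ge].sum() / vol.sum())


def difference_map(
    sol_a: Solution,
    sol_b: Solution,
    mesh: TetMesh,
    roi_labels: Iterable[str] | None = None,
) -> FieldDifference:
    """Signed field-strength difference |E_A| - |E_B| per element.

    Antisymmetric under swapping the two solutions; the summary median is
    volume-weighted over the ROI (whole mesh by default).
    """
    delta = sol_a.norm_E() - sol_b.norm_E()
    mask = _roi_mask(mesh, roi_labels)
    med = weighted_quantile(delta[mask], mesh.element_volumes()[mask], 0.5)
    return FieldDifference(delta_normE=delta, median_delta_Vpm=med)


def fit_interior_field(
    mesh: TetMesh,
    V: np.ndarray,
    center: Sequence[float],
    radius_mm: float,
) -> float:
    """|E| of the best-fit uniform field inside a ball of nodes.

    Least-squares fit of V = a - E . x over all nodes within ``radius_mm``
    of ``center``; the right way to measure the (theoretically uniform)
    interior field of a spherical inclusion without picking up the
    voxelised-interface staircase carried by per-element gradients.
    """
    sel = np.linalg.norm(mesh.nodes - np.asarray(center, dtype=float), axis=1) < radius_mm
    if sel.sum() < 8:
        raise ValueError("too few nodes inside the fit radius")
    X = np.column_stack([np.ones(int(sel.sum())), mesh.nodes[sel] * 1e-3])
    coef, *_ = np.linalg.lstsq(X, V[sel], rcond=None)
    return float(np.linalg.norm(coef[1:]))


def hotspot_extract(
    solution: Solution,
    mesh: TetMesh,
    percentile: float,
    roi_labels: Iterable[str] | None = None,
) -> np.ndarray:
    """Element ids with |E| strictly above the volume-weighted percentile.

    ``percentile`` is in [0, 100); 0 returns every ROI element.  For a
    perfectly uniform field any positive percentile returns an empty set
    (nothing lies strictly above the threshold).
    """
    if not 0.0 <= percentile < 100.0:
        raise ValueError("percentile must be in [0, 100)")
    mask = _roi_mask(mesh, roi_labels)
    ids = np.nonzero(mask)[0]
    if percentile == 0.0:
        return ids
    normE = solution.norm_E()[mask]
    thr = weighted_quantile(normE, mesh.element_volumes()[mask], percentile / 100.0)
    return ids[normE > thr]
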