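"""Structure rasterization, cumulative DVHs, and the reported dose metrics.

Volumes follow the voxel-center rule: a structure's volume is the number
of voxels whose centers fall inside its contours times the voxel volume.
Rasterization uses the even-odd (crossing-number) rule per slice, with a
voxel center lying exactly on a contour edge counted as inside
(deterministic tie-break).

Metric conventions (all deterministic, documented here once):

* a voxel counts toward a dose level when its dose is >= the level;
* V_x%  — percent of the structure volume receiving >= x% of prescription;
* D_x%  — largest dose (as % of prescription) such that at least x% of the
  structure volume receives >= it: the ceil(x/100 * n)-th hottest voxel;
* D_v cm3 — minimum dose among the hottest ceil(v / voxel volume) voxels,
  i.e. the discrete order statistic without interpolation;
* DHI = 1 - V150/V100 with absolute volumes of the body structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .engine import DoseGrid
from .errors import (EmptyStructureError, InsufficientVolumeError,
                     InvalidInputError, UndefinedMetricError)

__all__ = [
    "StructureMask",
    "DVHCurve",
    "rasterize_structure",
    "cumulative_dvh",
    "evaluate_metric",
    "dhi",
    "structure_doses",
]


@dataclass
class StructureMask:
    """Named binary voxel mask on the shared grid (TG-263-style label)."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 3:
            raise InvalidInputError("structure mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_cm3(self, voxel_volume_cm3: float) -> float:
        return self.n_voxels * voxel_volume_cm3


@dataclass
class DVHCurve:
    """Exact empirical cumulative DVH of one structure.

    ``dose`` is the sorted multiset of in-structure voxel doses (Gy);
    ``volume_fraction[i]`` is the fraction of the structure receiving a
    dose >= ``dose[i]``.  ``prescription`` (Gy) is kept for normalization.
    """

    dose: np.ndarray
    volume_fraction: np.ndarray
    prescription: float

    def fraction_at(self, dose_gy: float) -> float:
        """Volume fraction receiving >= ``dose_gy`` (the >= convention)."""
        n = self.dose.size
        return float((n - np.searchsorted(self.dose, dose_gy, "left")) / n)


def _points_in_polygon(px: np.ndarray, py: np.ndarray,
                       poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd test; points on an edge count as inside."""
    inside = np.zeros(px.shape, bool)
    on_edge = np.zeros(px.shape, bool)
    x0s, y0s = poly[:, 0], poly[:, 1]
    x1s, y1s = np.roll(x0s, -1), np.roll(y0s, -1)
    for x0, y0, x1, y1 in zip(x0s, y0s, x1s, y1s):
        # crossing-number update for the open edge
        cond = (y0 > py) != (y1 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= cond & (px < x_int)
        # boundary detection (point on the closed segment)
        ex, ey = x1 - x0, y1 - y0
        ln2 = ex * ex + ey * ey
        if ln2 == 0.0:
            on_edge |= (px == x0) & (py == y0)
            continue
        cross = (px - x0) * ey - (py - y0) * ex
        tpar = ((px - x0) * ex + (py - y0) * ey) / ln2
        tol = 1e-9 * math.sqrt(ln2)
        on_edge |= (np.abs(cross) <= tol * math.sqrt(ln2)) \
            & (tpar >= -1e-12) & (tpar <= 1 + 1e-12)
    return inside | on_edge


def _polygon_self_intersects(poly: np.ndarray) -> bool:
    n = len(poly)
    segs = [(poly[i], poly[(i + 1) % n]) for i in range(n)]

    def seg_cross(a, b, c, d):
        def orient(p, q, r):
            return np.sign((q[0] - p[0]) * (r[1] - p[1])
                           - (q[1] - p[1]) * (r[0] - p[0]))
        return (orient(a, b, c) != orient(a, b, d)
                and orient(c, d, a) != orient(c, d, b)
                and 0 not in (orient(a, b, c), orient(a, b, d)))

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if seg_cross(*segs[i], *segs[j]):
                return True
    return False


def rasterize_structure(
    name: str,
    contours: list[tuple[float, np.ndarray]],
    grid_shape,
    voxel_size,
    origin,
    check_self_intersection: bool = False,
) -> StructureMask:
    """Rasterize per-slice closed polygons with the voxel-center rule.

    ``contours`` is a list of ``(z_mm, polygon)`` pairs, each polygon an
    (N, 2) array of (x, y) mm vertices of a closed planar contour (the
    closing edge is implicit).  A voxel is included iff its center lies
    inside the polygon of its slice under the even-odd rule; centers on
    the contour are inside.  Multiple polygons on one slice XOR (even-odd
    across polygons), so holes are supported.
    """
    voxel_size = np.asarray(voxel_size, float).reshape(3)
    origin = np.asarray(origin, float).reshape(3)
    nx, ny, nz = grid_shape
    mask = np.zeros((nx, ny, nz), bool)
    cx = origin[0] + np.arange(nx) * voxel_size[0]
    cy = origin[1] + np.arange(ny) * voxel_size[1]
    px, py = np.meshgrid(cx, cy, indexing="ij")
    for z_mm, poly in contours:
        poly = np.asarray(poly, float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise InvalidInputError("polygon must be (N>=3, 2)")
        if check_self_intersection and _polygon_self_intersects(poly):
            warnings.warn(f"structure {name!r}: self-intersecting contour "
                          f"at z={z_mm}; even-odd rule applied", stacklevel=2)
        k = int(round((z_mm - origin[2]) / voxel_size[2]))
        if not 0 <= k < nz:
            continue
        mask[:, :, k] ^= _points_in_polygon(px, py, poly)
    return StructureMask(name, mask)


def structure_doses(dose: DoseGrid | np.ndarray,
                    mask: StructureMask) -> np.ndarray:
    """In-structure voxel doses as a flat array (Gy)."""
    d = dose.dose if isinstance(dose, DoseGrid) else np.asarray(dose)
    if d.shape != mask.mask.shape:
        raise InvalidInputError("dose grid and mask shapes differ")
    vals = d[mask.mask]
    if vals.size == 0:
        raise EmptyStructureError(f"structure {mask.name!r} is empty")
    return vals


def cumulative_dvh(dose: DoseGrid | np.ndarray, mask: StructureMask,
                   prescription: float) -> DVHCurve:
    """Exact (unbinned) cumulative DVH from the in-mask dose multiset."""
    vals = np.sort(structure_doses(dose, mask))
    frac = 1.0 - np.arange(vals.size) / vals.size
    return DVHCurve(dose=vals, volume_fraction=frac,
                    prescription=prescription)


def evaluate_metric(
    doses: np.ndarray,
    metric: str,
    prescription: float,
    voxel_volume_cm3: float | None = None,
) -> float:
    """Evaluate one DVH metric on a flat voxel-dose array.

    ``metric`` is a TG-263-style string: ``"V200%"``, ``"V90%"``,
    ``"D90%"``, ``"D0.1cm3"``.  V-metrics return percent of structure
    volume, D-metrics percent of prescription.
    """
    doses = np.asarray(doses, float)
    if doses.size == 0:
        raise EmptyStructureError("no voxel doses supplied")
    m = metric.strip()
    if m.startswith("V") and m.endswith("%"):
        x = float(m[1:-1])
        level = x / 100.0 * prescription
        return float(np.mean(doses >= level) * 100.0)
    if m.startswith("D") and m.endswith("%"):
        x = float(m[1:-1])
        n = doses.size
        kk = max(1, math.ceil(x / 100.0 * n))
        if kk > n:
            raise InvalidInputError(f"{metric}: x > 100%")
        d = np.partition(doses, n - kk)[n - kk]
        return float(d / prescription * 100.0)
    if m.startswith("D") and m.endswith("cm3"):
        if voxel_volume_cm3 is None:
            raise InvalidInputError("absolute-volume metric needs the voxel "
                                    "volume")
        v = float(m[1:-3])
        kk = math.ceil(v / voxel_volume_cm3 - 1e-9)
        kk = max(1, kk)
        n = doses.size
        if n * voxel_volume_cm3 < v:
            raise InsufficientVolumeError(
                f"structure volume {n * voxel_volume_cm3:.3f} cm3 < {v} cm3")
        d = np.partition(doses, n - kk)[n - kk]
        return float(d / prescription * 100.0)
    raise InvalidInputError(f"unrecognized metric spec {metric!r}")


def dhi(dose: DoseGrid | np.ndarray, body_mask: StructureMask,
        prescription: float) -> float:
    """Dose homogeneity index 1 - V150/V100 (absolute body volumes)."""
    vals = structure_doses(dose, body_mask)
    v100 = int(np.sum(vals >= prescription))
    if v100 == 0:
        raise UndefinedMetricError("DHI undefined: V100 is zero")
    v150 = int(np.sum(vals >= 1.5 * prescription))
    return 1.0 - v150 / v100
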