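"""Seed-reproducible synthetic breast HDR brachytherapy cases.

Each case emulates the inputs of a post-lumpectomy interstitial implant:
a hemispherical breast of adipose-range HU resting on a soft-tissue chest
wall over a low-density lung slab, surrounded by air; blobby glandular
regions; an excision cavity; a skin rim; parallel interstitial catheters
carrying dwell positions; and a dwell-time optimization performed with a
water kernel — deliberately, because clinical plans are optimized under
all-water assumptions and then re-evaluated here under both schemes.

The generator reproduces the statistical structure the analysis assumes
(targets near tissue-air interfaces, 10-25 catheters, adipose/gland
mixture), not CT realism: no beam hardening, no anatomical texture beyond
Gaussian HU noise, no curved free-hand catheters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import nnls

from .dvh import StructureMask
from .errors import DegenerateCaseError, ValidationError
from .materials import (Scheme, VoxelPhantom, build_phantom,
                        load_calibration_curve)
from .source import (DEFAULT_FRACTIONS, DEFAULT_PRESCRIPTION_GY,
                     DEFAULT_SK_U, DwellPlan)

__all__ = [
    "CaseParams",
    "CaseBundle",
    "generate_phantom",
    "generate_structures",
    "generate_plan",
    "generate_cohort",
    "build_case",
    "case_phantoms",
]

# representative HU by tissue (mean of the Gaussian noise model)
_HU_AIR = -1000.0
_HU_LUNG = -740.0
_HU_CHEST = 40.0
_HU_ADIPOSE = -76.0
_HU_GLAND = -42.0
_HU_CAVITY = 20.0
_HU_MARKER = 700.0
_HU_NOISE_SD = 10.0

#: approximate Ir-192 dose-rate constant used only by the water planning
#: kernel, Gy/h at 1 cm per U
_KERNEL_LAMBDA = 1.109e-2
#: effective attenuation of the water kernel, 1/mm
_KERNEL_MU = 0.002
#: relative weight of the dwell-time smoothness penalty in plan fitting,
#: calibrated once so generated plans match typical clinical plan quality
#: (PTV V200 ~ 9-10%, V100 ~ 92-94%, D90 ~ 103-104% under D_w,w)
_PLAN_SMOOTHING = 1.0


@dataclass(frozen=True)
class CaseParams:
    """Geometry and sampling parameters of one synthetic case (mm)."""

    breast_radius_mm: float = 70.0
    chest_wall_thickness_mm: float = 15.0
    lung_extent_mm: float = 40.0
    skin_thickness_mm: float = 2.0
    cavity_center_mm: tuple[float, float, float] = (0.0, 0.0, 30.0)
    cavity_radii_mm: tuple[float, float, float] = (15.0, 15.0, 12.0)
    glandularity: float = 0.3
    catheter_count: int = 16
    catheter_spacing_mm: float = 10.0
    dwell_spacing_mm: float = 5.0
    markers: bool = False
    seed: int = 0
    voxel_size_mm: float = 2.0
    ctv_margin_mm: float = 10.0
    ptv_margin_mm: float = 15.0
    air_margin_mm: float = 10.0

    def __post_init__(self) -> None:
        if not 10 <= self.catheter_count <= 25:
            raise ValidationError("catheter count must be in [10, 25]")
        if not 0.0 <= self.glandularity <= 1.0:
            raise ValidationError("glandularity must be in [0, 1]")
        for val in (self.breast_radius_mm, self.chest_wall_thickness_mm,
                    self.lung_extent_mm, self.skin_thickness_mm,
                    self.dwell_spacing_mm, self.voxel_size_mm):
            if not val > 0:
                raise ValidationError("all lengths must be positive")
        c = np.asarray(self.cavity_center_mm, float)
        r = np.asarray(self.cavity_radii_mm, float)
        if np.any(r <= 0):
            raise ValidationError("cavity radii must be positive")
        # cavity strictly inside the breast hemisphere (z >= 0 dome)
        if c[2] - r[2] < 1.0:
            raise ValidationError("cavity extends into the chest wall")
        if np.linalg.norm(c) + r.max() >= self.breast_radius_mm - 1.0:
            raise ValidationError("cavity not strictly inside the breast")


@dataclass
class CaseBundle:
    """Everything needed to run one case end to end."""

    case_id: str
    params: CaseParams
    hu: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    breast_mask: np.ndarray
    glandular_mask: np.ndarray
    structures: dict[str, StructureMask]
    plan: DwellPlan
    masks: dict[str, np.ndarray] = field(default_factory=dict)


def _grid_geometry(p: CaseParams):
    """Grid shape/origin: breast dome centred at the coordinate origin,
    chest-wall top plane at z = 0, lung below, air margin all round."""
    d = p.voxel_size_mm
    m = p.air_margin_mm
    r = p.breast_radius_mm
    xy_half = r + m
    z_lo = -(p.chest_wall_thickness_mm + p.lung_extent_mm)
    z_hi = r + m
    nx = int(np.ceil(2 * xy_half / d))
    nz = int(np.ceil((z_hi - z_lo) / d))
    origin = np.array([-xy_half + 0.5 * d, -xy_half + 0.5 * d,
                       z_lo + 0.5 * d])
    return (nx, nx, nz), np.array([d, d, d]), origin


def _coords(shape, voxel_size, origin):
    ax = [origin[i] + np.arange(shape[i]) * voxel_size[i] for i in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def _catheter_layout(p: CaseParams):
    """Deterministic (y, z) lattice of parallel catheters (running along x)
    covering the cavity plus the PTV margin, nearest-first to the cavity."""
    cy, cz = p.cavity_center_mm[1], p.cavity_center_mm[2]
    ry, rz = p.cavity_radii_mm[1], p.cavity_radii_mm[2]
    reach_y = ry + p.ptv_margin_mm
    reach_z = rz + p.ptv_margin_mm
    # spacing adapted so the requested count covers the whole target
    # cross-section (clinical implants spread catheters over the target,
    # they do not cluster them centrally)
    area = np.pi * reach_y * reach_z
    spacing = float(np.sqrt(area / p.catheter_count))
    spacing = min(spacing, 1.5 * p.catheter_spacing_mm)
    for _ in range(12):
        ys = cy + spacing * (np.arange(-np.ceil(reach_y / spacing),
                                       np.ceil(reach_y / spacing) + 1)
                             + 0.5)
        zs = cz + spacing * (np.arange(-np.ceil(reach_z / spacing),
                                       np.ceil(reach_z / spacing) + 1)
                             + 0.5)
        yy, zz = np.meshgrid(ys, zs, indexing="ij")
        cand = np.column_stack([yy.ravel(), zz.ravel()])
        cand = cand[cand[:, 1] > 2.0]  # stay above the chest wall
        # keep lines whose (y, z) lies within the dilated cavity ellipse
        u = ((cand[:, 0] - cy) / reach_y) ** 2 \
            + ((cand[:, 1] - cz) / reach_z) ** 2
        cand = cand[u <= 1.0 + 1e-9]
        if len(cand) >= p.catheter_count:
            # drop the outermost extras, keeping uniform interior coverage
            d2 = ((cand[:, 0] - cy) / reach_y) ** 2 \
                + ((cand[:, 1] - cz) / reach_z) ** 2
            order = np.lexsort((cand[:, 1], cand[:, 0], d2))
            return cand[order[: p.catheter_count]]
        spacing *= 0.92
    raise DegenerateCaseError("could not place the requested number of "
                              "catheters through the target")


def generate_phantom(p: CaseParams):
    """Synthetic CT: returns (hu, masks, voxel_size, origin).

    ``masks`` holds boolean volumes: body, breast, glandular, cavity,
    chest_wall, lung (and marker when enabled).  Identical seeds give
    voxelwise-identical output.
    """
    shape, voxel_size, origin = _grid_geometry(p)
    x, y, z = _coords(shape, voxel_size, origin)
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0x9E37]))

    r = p.breast_radius_mm
    breast = (z >= 0) & (x ** 2 + y ** 2 + z ** 2 <= r ** 2)
    # chest wall and lung span the full lateral grid: the thorax continues
    # beyond the scoring volume, so no artificial lateral air gap
    chest = (z < 0) & (z >= -p.chest_wall_thickness_mm)
    lung = (z < -p.chest_wall_thickness_mm) \
        & (z >= -(p.chest_wall_thickness_mm + p.lung_extent_mm))

    c = np.asarray(p.cavity_center_mm)
    cr = np.asarray(p.cavity_radii_mm)
    cavity = (((x - c[0]) / cr[0]) ** 2 + ((y - c[1]) / cr[1]) ** 2
              + ((z - c[2]) / cr[2]) ** 2) <= 1.0
    cavity &= breast

    # blobby glandular regions occupying the requested volume fraction
    gland = np.zeros(shape, bool)
    breast_tissue = breast & ~cavity
    if p.glandularity > 0 and breast_tissue.any():
        noise = rng.standard_normal(shape)
        sigma_vox = 4.0 / p.voxel_size_mm
        smooth = ndimage.gaussian_filter(noise, sigma_vox)
        vals = smooth[breast_tissue]
        thr = np.quantile(vals, 1.0 - p.glandularity)
        gland = breast_tissue & (smooth >= thr)

    hu = np.full(shape, _HU_AIR)
    hu[lung] = _HU_LUNG
    hu[chest] = _HU_CHEST
    hu[breast_tissue] = _HU_ADIPOSE
    hu[gland] = _HU_GLAND
    hu[cavity] = _HU_CAVITY
    body = breast | chest | lung
    hu[body] += _HU_NOISE_SD * rng.standard_normal(shape)[body]

    masks = {"body": body, "breast": breast_tissue, "glandular": gland,
             "cavity": cavity, "chest_wall": chest, "lung": lung}

    if p.markers:
        marker = np.zeros(shape, bool)
        for cy_mm, cz_mm in _catheter_layout(p):
            j = int(round((cy_mm - origin[1]) / voxel_size[1]))
            k = int(round((cz_mm - origin[2]) / voxel_size[2]))
            if not (0 <= j < shape[1] and 0 <= k < shape[2]):
                continue
            for x_mm in np.arange(-r, r, 10.0):
                i = int(round((x_mm - origin[0]) / voxel_size[0]))
                if 0 <= i < shape[0] and breast[i, j, k]:
                    marker[i, j, k] = True
        hu[marker] = _HU_MARKER
        # markers are excluded from the breast override so the calibration
        # curve classifies them as small bony features
        masks["breast"] = masks["breast"] & ~marker
        masks["marker"] = marker

    return hu, masks, voxel_size, origin


def generate_structures(p: CaseParams, masks: dict, voxel_size,
                        origin) -> dict[str, StructureMask]:
    """Target volumes and organs at risk from the phantom masks.

    PTV is the cavity expanded by a Euclidean ball of the PTV margin,
    restricted to breast-side tissue with the chest wall (and lung)
    excluded; PTV_EVAL additionally removes the 5 mm rim beneath the skin
    surface.  CTV uses the (configurable) CTV margin with the same
    clipping.  Skin is the outer rim of the body of the configured
    thickness.
    """
    body = masks["body"]
    cavity = masks["cavity"]
    if not cavity.any():
        raise DegenerateCaseError("empty excision cavity")
    sampling = tuple(np.asarray(voxel_size, float))
    dist_cavity = ndimage.distance_transform_edt(~cavity, sampling=sampling)
    dist_air = ndimage.distance_transform_edt(body, sampling=sampling)

    in_breast = body & ~masks["chest_wall"] & ~masks["lung"]
    ptv = (dist_cavity <= p.ptv_margin_mm) & in_breast
    ctv = (dist_cavity <= p.ctv_margin_mm) & in_breast
    skin = body & (dist_air <= p.skin_thickness_mm)
    ptv_eval = ptv & (dist_air > 5.0)
    if not ptv_eval.any():
        raise DegenerateCaseError("PTV_EVAL is empty")

    return {
        "cavity": StructureMask("Cavity", cavity),
        "ctv": StructureMask("CTV", ctv),
        "ptv": StructureMask("PTV", ptv),
        "ptv_eval": StructureMask("PTV_EVAL", ptv_eval),
        "skin": StructureMask("Skin", skin),
        "chest_wall": StructureMask("ChestWall", masks["chest_wall"]),
        "lung": StructureMask("Lungs", masks["lung"]),
        "body": StructureMask("Body", body),
    }


def _kernel_dose_rate(points, dwell_pos, sk_u):
    """Water planning kernel: Gy/s at each point from each dwell position.

    Inverse square with a mild exponential attenuation, anchored to an
    approximate dose-rate constant at 1 cm — the same style of all-water
    model a clinical optimizer uses.
    """
    diff = points[:, None, :] - dwell_pos[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=2))
    r = np.maximum(r, 1.0)
    c = sk_u * _KERNEL_LAMBDA / 3600.0
    return c * (10.0 / r) ** 2 * np.exp(-_KERNEL_MU * (r - 10.0))


def generate_plan(p: CaseParams, structures: dict[str, StructureMask],
                  voxel_size, origin,
                  prescription_gy: float = DEFAULT_PRESCRIPTION_GY,
                  fractions: int = DEFAULT_FRACTIONS,
                  sk_u: float = DEFAULT_SK_U) -> DwellPlan:
    """Dwell plan: parallel catheters through the PTV, water-kernel times.

    Dwells step along each catheter every ``dwell_spacing_mm`` inside the
    PTV plus a 5 mm margin.  Per-fraction dwell times come from a
    non-negative least-squares fit of the water kernel to the per-fraction
    prescription at sampled PTV surface points, then a global rescale so
    the kernel-predicted PTV D90 equals the prescription.
    """
    ptv = structures["ptv"].mask
    if not ptv.any():
        raise DegenerateCaseError("PTV is empty")
    voxel_size = np.asarray(voxel_size, float)
    origin = np.asarray(origin, float)
    lines = _catheter_layout(p)

    # PTV x-extent at each catheter (y, z)
    positions = []
    for cy_mm, cz_mm in lines:
        j = int(round((cy_mm - origin[1]) / voxel_size[1]))
        k = int(round((cz_mm - origin[2]) / voxel_size[2]))
        if not (0 <= j < ptv.shape[1] and 0 <= k < ptv.shape[2]):
            continue
        col = ptv[:, j, k]
        hit = np.nonzero(col)[0]
        if hit.size == 0:
            # parallel needle that misses the PTV at this plane: span the
            # cavity-level extent instead so the count is preserved
            x_lo = p.cavity_center_mm[0] - p.cavity_radii_mm[0]
            x_hi = p.cavity_center_mm[0] + p.cavity_radii_mm[0]
        else:
            x_lo = origin[0] + hit[0] * voxel_size[0] - 5.0
            x_hi = origin[0] + hit[-1] * voxel_size[0] + 5.0
        for x_mm in np.arange(x_lo, x_hi + 1e-9, p.dwell_spacing_mm):
            positions.append((x_mm, cy_mm, cz_mm))
    if not positions:
        raise DegenerateCaseError("no dwell positions inside the target")
    dwell_pos = np.asarray(positions, float)

    # surface points: PTV voxels adjacent to non-PTV
    eroded = ndimage.binary_erosion(ptv)
    surf = np.argwhere(ptv & ~eroded)
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0x51AB]))
    if len(surf) > 300:
        surf = surf[rng.choice(len(surf), 300, replace=False)]
    surf_mm = origin + surf * voxel_size

    per_fraction = prescription_gy / fractions
    a = _kernel_dose_rate(surf_mm, dwell_pos, sk_u)
    # Tikhonov-regularized non-negative fit pulled toward uniform times:
    # clinical optimizers penalize dwell-time spikes, which keeps the
    # high-dose volumes (V150/V200) near clinical levels
    n_d = a.shape[1]
    t_flat = per_fraction / np.maximum(a.sum(axis=1).mean(), 1e-30) \
        * np.ones(n_d)
    lam = _PLAN_SMOOTHING * np.linalg.norm(a, axis=0).mean() \
        * np.sqrt(len(surf_mm) / n_d)
    a_aug = np.vstack([a, lam * np.eye(n_d)])
    b_aug = np.concatenate(
        [np.full(len(surf_mm), per_fraction), lam * t_flat])
    times, _ = nnls(a_aug, b_aug)

    # global rescale: kernel-predicted PTV D90 = per-fraction prescription
    vox = np.argwhere(ptv)
    if len(vox) > 20000:
        vox = vox[rng.choice(len(vox), 20000, replace=False)]
    vox_mm = origin + vox * voxel_size
    pred = _kernel_dose_rate(vox_mm, dwell_pos, sk_u) @ times
    d90 = np.quantile(pred, 0.10)
    if d90 <= 0:
        raise DegenerateCaseError("water-kernel optimization failed")
    times = times * (per_fraction / d90)

    keep = times > 1e-4
    return DwellPlan(dwell_pos[keep], times[keep],
                     air_kerma_strength=sk_u,
                     prescription_dose=prescription_gy,
                     fractions=fractions)


def build_case(p: CaseParams, case_id: str | None = None) -> CaseBundle:
    """Generate phantom, structures and plan for one parameter set."""
    hu, masks, voxel_size, origin = generate_phantom(p)
    structures = generate_structures(p, masks, voxel_size, origin)
    plan = generate_plan(p, structures, voxel_size, origin)
    return CaseBundle(
        case_id=case_id or f"case{p.seed:05d}",
        params=p, hu=hu, voxel_size=voxel_size, origin=origin,
        breast_mask=masks["breast"], glandular_mask=masks["glandular"],
        structures=structures, plan=plan, masks=masks)


def case_phantoms(bundle: CaseBundle) -> tuple[VoxelPhantom, VoxelPhantom]:
    """The two phantoms of a case: (heterogeneous, unbound water)."""
    curve = load_calibration_curve()
    ph_mm = build_phantom(bundle.hu, bundle.voxel_size, bundle.origin,
                          curve=curve, scheme=Scheme.HETEROGENEOUS,
                          breast_mask=bundle.breast_mask,
                          glandular_mask=bundle.glandular_mask)
    ph_ww = build_phantom(bundle.hu, bundle.voxel_size, bundle.origin,
                          curve=curve, scheme=Scheme.WATER_UNBOUND)
    return ph_mm, ph_ww


def generate_cohort(n_cases: int, master_seed: int,
                    voxel_size_mm: float = 2.0,
                    markers: bool = False) -> list[CaseParams]:
    """Draw ``n_cases`` reproducible case parameter sets.

    Distributions (documented assumptions, not clinical statistics):
    breast radius U(50, 90) mm, glandularity U(0.1, 0.5), spherical cavity
    radius U(10, 25) mm, catheter count uniform integer 10-25, cavity
    position uniform within the region keeping it strictly inside the
    breast and clear of the chest wall.
    """
    if n_cases < 1:
        raise ValidationError("need at least one case")
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 0xC0]))
    out = []
    for i in range(n_cases):
        radius = rng.uniform(50.0, 90.0)
        gland = rng.uniform(0.1, 0.5)
        cav_r = rng.uniform(10.0, min(25.0, (radius - 8.0) / 2.5))
        n_cath = int(rng.integers(10, 26))
        # cavity surface sits 3-20 mm beneath the skin along a random
        # direction of the upper hemisphere (lumpectomy beds are commonly
        # superficial, which is what puts the target near the skin)
        gap = rng.uniform(3.0, 20.0)
        # keep the cavity clear of the chest wall even at zero polar angle
        gap = min(gap, radius - 2.0 * cav_r - 2.0)
        center = None
        for _try in range(30):
            theta = rng.uniform(0.0, np.deg2rad(60.0))
            phi = rng.uniform(0.0, 2.0 * np.pi)
            u = np.array([np.sin(theta) * np.cos(phi),
                          np.sin(theta) * np.sin(phi), np.cos(theta)])
            c = (radius - cav_r - gap) * u
            if c[2] - cav_r >= 2.0:
                center = c
                break
        if center is None:
            center = np.array([0.0, 0.0, radius - cav_r - gap])
        case_seed = int(rng.integers(0, 2 ** 31 - 1))
        out.append(CaseParams(
            breast_radius_mm=radius,
            cavity_center_mm=tuple(center),
            cavity_radii_mm=(cav_r, cav_r, cav_r),
            glandularity=gland,
            catheter_count=n_cath,
            markers=markers,
            seed=case_seed,
            voxel_size_mm=voxel_size_mm,
        ))
    return out
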