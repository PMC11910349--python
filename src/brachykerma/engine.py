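"""Monte Carlo collisional-kerma dose engine.

One engine computes both dose quantities compared by the package: run it on
a ``WATER_UNBOUND`` phantom for D_w,w and on a ``HETEROGENEOUS`` phantom for
D_m,m, with the same plan, spectrum and seed.  Dose is approximated by
collisional kerma (no electron transport; secondary-electron ranges are
short compared with the voxel size at Ir-192 energies) and scored with a
track-length estimator, in Gy for the full treatment course.

Statistical (Type A) uncertainty is estimated from batch statistics:
histories are split into B independent batches and the per-voxel batch
sums and sums of squares are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .errors import (EmptySelectionError, InvalidInputError, SimulationError,
                     ValidationError)
from .materials import Scheme, VoxelPhantom, load_materials
from .source import DwellPlan, PhotonSpectrum, decays_per_dwell
from .xs import build_material_table

__all__ = ["DoseGrid", "run_simulation", "trace_ray", "type_a_uncertainty"]

MEV_PER_G_TO_GY = 1.602176634e-10

#: atomic numbers used for the Rayleigh screening parameter
_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "Na": 11, "Mg": 12, "P": 15,
      "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20}
_A = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "Na": 22.990,
      "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
      "K": 39.098, "Ca": 40.078}
_A0_CM = 5.29177211e-9


@dataclass
class DoseGrid:
    """Per-voxel dose with batch accumulators for Type-A uncertainty.

    ``dose`` is in Gy for the whole course; ``batch_sums`` /
    ``batch_sum_squares`` hold per-voxel sums of per-batch dose
    contributions (same units) over ``n_batches`` batches.
    """

    dose: np.ndarray
    batch_sums: np.ndarray
    batch_sum_squares: np.ndarray
    n_batches: int
    n_histories: int
    scheme_label: str           # "D_w,w" or "D_m,m"
    voxel_size: np.ndarray
    origin: np.ndarray
    seed: int

    def standard_error(self) -> np.ndarray:
        """Per-voxel standard error of the total dose from batch spread."""
        b = self.n_batches
        var_b = (self.batch_sum_squares - self.batch_sums ** 2 / b) / (b - 1)
        return np.sqrt(np.maximum(var_b, 0.0) * b)


def _rayleigh_r2(material) -> float:
    """Z^2-weighted Wentzel screening radius squared (cm^2)."""
    num = 0.0
    den = 0.0
    for sym, w in material.elemental_composition.items():
        z = _Z[sym]
        atoms = w / _A[sym]
        r_tf = 0.885 * _A0_CM * z ** (-1.0 / 3.0)
        num += atoms * z * z * r_tf
        den += atoms * z * z
    return (num / den) ** 2


def _physics_stack(phantom: VoxelPhantom, n_fine: int = 1024):
    """Resample material cross sections onto a shared fine log-energy grid."""
    names = list(phantom.material_names)
    if "water" not in names:
        names.append("water")
        mats = dict(phantom.materials)
        mats["water"] = load_materials()["water"]
    else:
        mats = phantom.materials
    tables = [build_material_table(mats[n]) for n in names]
    e0, e1 = tables[0].energy[0], tables[0].energy[-1]
    fine = np.geomspace(e0, e1, n_fine)
    ln_e0 = np.log(fine[0])
    inv_dln_e = (n_fine - 1) / (np.log(fine[-1]) - np.log(fine[0]))

    def resample(vals, grid):
        return np.exp(np.interp(np.log(fine), np.log(grid), np.log(vals)))

    nmat = len(names)
    log_mu = np.empty((nmat, n_fine))
    log_muen = np.empty((nmat, n_fine))
    f_pe = np.empty((nmat, n_fine))
    f_ray = np.empty((nmat, n_fine))
    ray_r2 = np.empty(nmat)
    for m, (name, tab) in enumerate(zip(names, tables)):
        tot = resample(tab.mu_total, tab.energy)
        log_mu[m] = np.log(tot)
        log_muen[m] = np.log(resample(tab.mu_en, tab.energy))
        f_pe[m] = resample(tab.mu_photoelectric, tab.energy) / tot
        f_ray[m] = resample(tab.mu_rayleigh, tab.energy) / tot
        ray_r2[m] = _rayleigh_r2(mats[name])
    water_idx = names.index("water")
    return (ln_e0, inv_dln_e, n_fine, log_mu, log_muen, f_pe, f_ray,
            ray_r2, water_idx)


def _allocate(decays: np.ndarray, n_per_batch: int) -> np.ndarray:
    """Largest-remainder allocation of batch histories to dwells.

    Every dwell with positive decays gets at least one history so that the
    estimator stays unbiased under the per-dwell weighting.
    """
    frac = decays / decays.sum()
    ideal = frac * n_per_batch
    n = np.floor(ideal).astype(np.int64)
    short = n_per_batch - n.sum()
    order = np.argsort(-(ideal - n))
    n[order[:short]] += 1
    starved = (decays > 0) & (n == 0)
    for d in np.nonzero(starved)[0]:
        donor = int(np.argmax(n))
        if n[donor] <= 1:
            raise InvalidInputError("too few histories per batch to cover "
                                    "all active dwells")
        n[donor] -= 1
        n[d] += 1
    return n


def run_simulation(
    phantom: VoxelPhantom,
    plan: DwellPlan,
    spectrum: PhotonSpectrum,
    n_histories: int,
    n_batches: int = 10,
    seed: int = 0,
    primary_only: bool = False,
    estimator: str = "track-length",
    energy_cutoff_kev: float = 10.0,
    per_decay: bool = False,
) -> DoseGrid:
    """Transport ``n_histories`` decay histories and return the dose grid.

    Histories are allocated to dwells in proportion to their decays
    (air-kerma strength x dwell time), split evenly over ``n_batches``
    batches.  With ``per_decay=True`` the normalization step is skipped and
    doses are in MeV/g per decay (useful for benchmarks without a plan
    strength).  ``estimator`` selects ``"track-length"`` (default) or the
    analog ``"collision"`` cross-check estimator.
    """
    if n_batches < 2:
        raise InvalidInputError("need at least 2 batches")
    if n_histories < n_batches:
        raise InvalidInputError("need n_histories >= n_batches")
    if estimator not in ("track-length", "collision"):
        raise InvalidInputError(f"unknown estimator {estimator!r}")
    if plan.n_dwells == 0:
        raise ValidationError("empty plan")

    air_tab = build_material_table(load_materials()["air"])
    decays = decays_per_dwell(plan, spectrum, air_tab)
    if not np.any(decays > 0):
        raise ValidationError("all dwell times are zero")

    (ln_e0, inv_dln_e, n_fine, log_mu, log_muen, f_pe, f_ray, ray_r2,
     water_idx) = _physics_stack(phantom)

    n_per_batch = n_histories // n_batches
    dwell_hist_b = _allocate(decays, n_per_batch)
    n_total_per_dwell = dwell_hist_b * n_batches
    with np.errstate(divide="ignore", invalid="ignore"):
        dwell_weight = np.where(n_total_per_dwell > 0,
                                decays / np.maximum(n_total_per_dwell, 1), 0.0)
    if per_decay:
        dwell_weight = np.where(n_total_per_dwell > 0,
                                1.0 / np.maximum(n_total_per_dwell, 1), 0.0)
        dwell_weight *= (decays > 0)

    intensities = spectrum.intensities
    line_cdf = np.cumsum(intensities) / intensities.sum()
    line_e = spectrum.energies

    shape = phantom.grid_shape
    nvox = int(np.prod(shape))
    mat_flat = np.ascontiguousarray(phantom.material_index.reshape(nvox))
    rho_flat = np.ascontiguousarray(phantom.density.reshape(nvox))
    dx, dy, dz = phantom.voxel_size
    bx0 = phantom.origin[0] - 0.5 * dx
    by0 = phantom.origin[1] - 0.5 * dy
    bz0 = phantom.origin[2] - 0.5 * dz
    inv_vvox = 1.0 / phantom.voxel_volume_cm3

    conv = 1.0 if per_decay else MEV_PER_G_TO_GY * plan.fractions
    sums = np.zeros(nvox)
    sumsq = np.zeros(nvox)
    scheme_water = 1 if phantom.scheme is Scheme.WATER_UNBOUND else 0
    hid = 0
    for b in range(n_batches):
        batch_dose = np.zeros(nvox)
        hid = _kernel.run_batch(
            np.uint64(seed), np.uint64(hid),
            np.ascontiguousarray(plan.positions, np.float64),
            dwell_hist_b, dwell_weight,
            line_e, line_cdf, spectrum.total_intensity,
            mat_flat, rho_flat,
            shape[0], shape[1], shape[2], dx, dy, dz, bx0, by0, bz0,
            ln_e0, inv_dln_e, n_fine, log_mu, log_muen, f_pe, f_ray, ray_r2,
            water_idx, scheme_water,
            1 if primary_only else 0,
            1 if estimator == "collision" else 0,
            energy_cutoff_kev, inv_vvox, batch_dose)
        hid = int(hid)
        batch_dose *= conv
        if not np.all(np.isfinite(batch_dose)):
            raise SimulationError(f"non-finite dose in batch {b}")
        sums += batch_dose
        sumsq += batch_dose ** 2

    label = "D_w,w" if scheme_water else "D_m,m"
    return DoseGrid(
        dose=sums.reshape(shape),
        batch_sums=sums.reshape(shape),
        batch_sum_squares=sumsq.reshape(shape),
        n_batches=n_batches,
        n_histories=int(dwell_hist_b.sum()) * n_batches,
        scheme_label=label,
        voxel_size=phantom.voxel_size.copy(),
        origin=phantom.origin.copy(),
        seed=seed,
    )


def trace_ray(
    phantom: VoxelPhantom,
    origin,
    direction,
    max_length: float,
):
    """Exact voxel chords of a ray through the phantom grid.

    Returns ``(indices, chords)``: an (M, 3) integer array of traversed
    voxel indices in order and the matching chord lengths in mm.  The
    chords sum to the in-grid path length up to ``max_length``.
    """
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise InvalidInputError("zero direction vector")
    direction = direction / norm

    lo = phantom.origin - 0.5 * phantom.voxel_size
    hi = lo + np.array(phantom.grid_shape) * phantom.voxel_size
    t0, t1 = 0.0, float(max_length)
    for ax in range(3):
        if direction[ax] != 0.0:
            ta = (lo[ax] - origin[ax]) / direction[ax]
            tb = (hi[ax] - origin[ax]) / direction[ax]
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
        elif not (lo[ax] < origin[ax] < hi[ax]):
            return np.empty((0, 3), np.int64), np.empty(0)
    if t1 <= t0:
        return np.empty((0, 3), np.int64), np.empty(0)

    # all plane crossings inside (t0, t1)
    ts = [np.array([t0, t1])]
    for ax in range(3):
        if direction[ax] == 0.0:
            continue
        planes = lo[ax] + np.arange(phantom.grid_shape[ax] + 1) \
            * phantom.voxel_size[ax]
        t_cross = (planes - origin[ax]) / direction[ax]
        ts.append(t_cross[(t_cross > t0) & (t_cross < t1)])
    t_all = np.unique(np.concatenate(ts))
    mids = 0.5 * (t_all[:-1] + t_all[1:])
    pts = origin[None, :] + mids[:, None] * direction[None, :]
    idx = np.floor((pts - lo[None, :]) / phantom.voxel_size[None, :])
    idx = idx.astype(np.int64)
    chords = np.diff(t_all)
    keep = chords > 1e-12
    return idx[keep], chords[keep]


def type_a_uncertainty(
    dose: DoseGrid,
    reference_dose: float,
    band: float = 0.01,
) -> float:
    """Mean relative Type-A uncertainty (percent) on an isodose band.

    Averages (standard error / dose) x 100 over voxels whose dose lies
    within ``reference_dose * (1 +/- band)`` — e.g. the 100% isodose
    surface when ``reference_dose`` is the prescription.
    """
    if dose.n_batches < 2:
        raise InvalidInputError("need >= 2 batches for Type A uncertainty")
    d = dose.dose
    sel = (d >= reference_dose * (1.0 - band)) \
        & (d <= reference_dose * (1.0 + band)) & (d > 0)
    if not np.any(sel):
        raise EmptySelectionError("no voxels inside the dose band")
    se = dose.standard_error()
    return float(np.mean(se[sel] / d[sel]) * 100.0)
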