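"""Tissue materials, HU calibration, and voxel phantom construction.

Two tissue-assignment schemes are supported, mirroring the two dose
quantities compared throughout the package:

* ``Scheme.WATER_UNBOUND`` — every voxel (patient and surrounding air) is
  water at unit density, and transport outside the grid continues in an
  analytic infinite water bath.  Doses computed this way are
  dose-to-water-in-water, D_w,w, emulating the infinite homogeneous water
  medium assumed by TG-43-style clinical planning.
* ``Scheme.HETEROGENEOUS`` — each voxel gets a tissue class and mass
  density from a Hounsfield-unit calibration curve, with breast voxels
  overridden to adipose or a 50/50 adipose–gland mixture.  Doses are
  dose-to-medium-in-medium, D_m,m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError, InvalidMixtureError, ValidationError

__all__ = [
    "Material",
    "CalibrationCurve",
    "Scheme",
    "VoxelPhantom",
    "load_materials",
    "load_calibration_curve",
    "mix_materials",
    "hu_to_density",
    "classify_hu",
    "build_phantom",
    "ADIPOSE_GLAND_MIX",
]

#: name given to the 50/50 adipose-gland mixture used for high-glandularity
#: breast regions
ADIPOSE_GLAND_MIX = "adipose_gland_5050"

_FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class Material:
    """A homogeneous material: elemental mass fractions and nominal density.

    Parameters
    ----------
    name:
        Identifier used in phantoms and cross-section tables.
    elemental_composition:
        Mapping of element symbol to mass fraction; fractions must sum to 1.
    nominal_density:
        Bulk density in g/cm^3 (per-voxel densities may differ).
    """

    name: str
    elemental_composition: Mapping[str, float]
    nominal_density: float

    def __post_init__(self) -> None:
        fracs = np.array(list(self.elemental_composition.values()), float)
        if fracs.size == 0:
            raise ValidationError(f"material {self.name!r} has no elements")
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise ValidationError(
                f"material {self.name!r}: mass fractions outside [0, 1]")
        if abs(fracs.sum() - 1.0) > _FRACTION_TOL:
            raise ValidationError(
                f"material {self.name!r}: mass fractions sum to "
                f"{fracs.sum():.8f}, not 1")
        if not self.nominal_density > 0:
            raise ValidationError(
                f"material {self.name!r}: non-positive density")


def _read_data_text(filename: str) -> str:
    return (resources.files("brachykerma") / "data" / filename).read_text()


def load_materials(path: str | None = None) -> dict[str, Material]:
    """Load a material table from the bundled config or a user file.

    The format is a sequence of blocks::

        material <name> density <g/cm3>
        <element> <mass fraction>
        ...

    Blank lines and ``#`` comments are ignored.
    """
    if path is None:
        text = _read_data_text("materials.txt")
    else:
        with open(path) as fh:
            text = fh.read()
    materials: dict[str, Material] = {}
    name: str | None = None
    density = 0.0
    comp: dict[str, float] = {}

    def flush() -> None:
        if name is not None:
            materials[name] = Material(name, dict(comp), density)

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "material":
            flush()
            if len(parts) != 4 or parts[2] != "density":
                raise ValidationError(f"bad material header: {raw!r}")
            name, density, comp = parts[1], float(parts[3]), {}
        else:
            if name is None:
                raise ValidationError(f"element line before header: {raw!r}")
            comp[parts[0]] = float(parts[1])
    flush()
    return materials


def mix_materials(
    components: Sequence[Material],
    mass_fractions: Sequence[float],
    name: str | None = None,
) -> Material:
    """Mix materials by mass.

    Elemental fractions are mass-fraction-weighted means; the nominal
    density is the mass-weighted harmonic mean (volumes add when masses
    are combined at fixed component densities).
    """
    if len(components) == 0:
        raise InvalidInputError("mix_materials: empty component list")
    if len(components) != len(mass_fractions):
        raise InvalidInputError(
            "mix_materials: components and fractions differ in length")
    w = np.asarray(mass_fractions, float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > _FRACTION_TOL:
        raise InvalidMixtureError(
            f"mass fractions must be non-negative and sum to 1, got {w}")
    if len(components) == 1:
        only = components[0]
        return Material(name or only.name,
                        dict(only.elemental_composition),
                        only.nominal_density)
    comp: dict[str, float] = {}
    for mat, wi in zip(components, w):
        for el, f in mat.elemental_composition.items():
            comp[el] = comp.get(el, 0.0) + wi * float(f)
    inv_rho = float(np.sum(w / np.array([m.nominal_density for m in components])))
    if name is None:
        name = "+".join(f"{wi:g}*{m.name}" for m, wi in zip(components, w))
    return Material(name, comp, 1.0 / inv_rho)


@dataclass(frozen=True)
class CalibrationCurve:
    """HU -> (mass density, tissue class) calibration.

    ``anchors`` is an ordered list of (HU, density g/cm^3, material name)
    with strictly increasing HU and non-negative density.  Density is
    interpolated piecewise-linearly between anchors and clamped outside
    them.  Tissue classes partition the HU axis: the boundary between two
    classes lies at the midpoint between the adjacent anchors of different
    class, and a HU exactly on a boundary belongs to the higher-HU class.
    """

    anchors: tuple[tuple[float, float, str], ...]
    _edges: np.ndarray = field(init=False, repr=False, compare=False)
    _classes: tuple[str, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValidationError("calibration curve needs >= 2 anchors")
        hu = np.array([a[0] for a in self.anchors], float)
        rho = np.array([a[1] for a in self.anchors], float)
        if not np.all(np.diff(hu) > 0):
            raise ValidationError("anchor HU values must strictly increase")
        if np.any(rho < 0):
            raise ValidationError("anchor densities must be non-negative")
        edges = []
        classes = [self.anchors[0][2]]
        for (h0, _, m0), (h1, _, m1) in zip(self.anchors, self.anchors[1:]):
            if m1 != m0:
                edges.append(0.5 * (h0 + h1))
                classes.append(m1)
        object.__setattr__(self, "_edges", np.array(edges, float))
        object.__setattr__(self, "_classes", tuple(classes))

    @property
    def hu(self) -> np.ndarray:
        return np.array([a[0] for a in self.anchors], float)

    @property
    def density(self) -> np.ndarray:
        return np.array([a[1] for a in self.anchors], float)

    @property
    def class_names(self) -> tuple[str, ...]:
        return self._classes

    def class_index(self, hu: np.ndarray | float) -> np.ndarray:
        """Index into :meth:`class_names` for each HU (vectorized)."""
        return np.searchsorted(self._edges, np.asarray(hu, float),
                               side="right")


def load_calibration_curve(path: str | None = None) -> CalibrationCurve:
    """Load the bundled default calibration curve or a user-supplied one."""
    if path is None:
        text = _read_data_text("hu_calibration.txt")
    else:
        with open(path) as fh:
            text = fh.read()
    anchors = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        hu_s, rho_s, mat = line.split()
        anchors.append((float(hu_s), float(rho_s), mat))
    return CalibrationCurve(tuple(anchors))


def hu_to_density(hu: np.ndarray | float, curve: CalibrationCurve):
    """Piecewise-linear density interpolation, clamped at the end anchors."""
    out = np.interp(np.asarray(hu, float), curve.hu, curve.density)
    return float(out) if np.isscalar(hu) else out


def classify_hu(hu: float, curve: CalibrationCurve) -> str:
    """Tissue class containing ``hu`` (boundary HU -> higher-HU class)."""
    return curve.class_names[int(curve.class_index(float(hu)))]


class Scheme(Enum):
    """Tissue-assignment scheme: all-water unbound phantom vs CT tissues."""

    WATER_UNBOUND = "ww"
    HETEROGENEOUS = "mm"


@dataclass
class VoxelPhantom:
    """Voxel grid with per-voxel material index and mass density.

    Voxel (i, j, k) is centred at ``origin + (i, j, k) * voxel_size`` (mm,
    patient coordinates).  ``material_names[material_index[v]]`` names the
    medium of voxel v; ``materials`` carries the full composition table so
    cross sections can be built for exactly the media present.
    """

    material_index: np.ndarray
    density: np.ndarray
    material_names: tuple[str, ...]
    materials: dict[str, Material]
    voxel_size: np.ndarray
    origin: np.ndarray
    scheme: Scheme

    def __post_init__(self) -> None:
        self.material_index = np.ascontiguousarray(self.material_index,
                                                   dtype=np.int16)
        self.density = np.ascontiguousarray(self.density, dtype=np.float64)
        self.voxel_size = np.asarray(self.voxel_size, float).reshape(3)
        self.origin = np.asarray(self.origin, float).reshape(3)
        if self.material_index.shape != self.density.shape:
            raise ValidationError("material_index/density shape mismatch")
        if self.material_index.ndim != 3:
            raise ValidationError("phantom arrays must be 3-D")
        if np.any(self.density < 0):
            raise ValidationError("negative density voxel")
        if (self.material_index.min() < 0
                or self.material_index.max() >= len(self.material_names)):
            raise ValidationError("material_index outside material table")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.material_index.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size)) * 1e-3

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        n = self.grid_shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]


def build_phantom(
    hu_volume: np.ndarray,
    voxel_size,
    origin,
    curve: CalibrationCurve | None = None,
    scheme: Scheme = Scheme.HETEROGENEOUS,
    breast_mask: np.ndarray | None = None,
    glandular_mask: np.ndarray | None = None,
    materials: dict[str, Material] | None = None,
) -> VoxelPhantom:
    """Build a :class:`VoxelPhantom` from a HU volume under one scheme.

    Under ``WATER_UNBOUND`` the HU content is ignored: every voxel becomes
    water at density 1.0 (air included), emulating the unbound water
    phantom.  Under ``HETEROGENEOUS`` each voxel gets its calibration-curve
    class and interpolated density, except breast voxels: inside
    ``breast_mask`` the composition is adipose, or the 50/50 adipose-gland
    mass mixture inside ``glandular_mask`` (density still from the curve).
    """
    hu_volume = np.asarray(hu_volume)
    if hu_volume.ndim != 3:
        raise InvalidInputError("hu_volume must be 3-D")
    if materials is None:
        materials = load_materials()
    if curve is None:
        curve = load_calibration_curve()
    for mask, label in ((breast_mask, "breast_mask"),
                        (glandular_mask, "glandular_mask")):
        if mask is not None and mask.shape != hu_volume.shape:
            raise InvalidInputError(f"{label} shape differs from hu_volume")

    if scheme is Scheme.WATER_UNBOUND:
        names = ("water",)
        mats = {"water": materials["water"]}
        idx = np.zeros(hu_volume.shape, np.int16)
        rho = np.ones(hu_volume.shape, float)
        return VoxelPhantom(idx, rho, names, mats, voxel_size, origin, scheme)

    mix = mix_materials([materials["adipose"], materials["gland"]],
                        [0.5, 0.5], name=ADIPOSE_GLAND_MIX)
    mats = dict(materials)
    mats[ADIPOSE_GLAND_MIX] = mix
    names = tuple(curve.class_names) + tuple(
        n for n in ("adipose", ADIPOSE_GLAND_MIX)
        if n not in curve.class_names)
    name_to_idx = {n: i for i, n in enumerate(names)}
    for n in names:
        if n not in mats:
            raise ValidationError(f"calibration class {n!r} not in materials")

    cls = curve.class_index(hu_volume)
    idx = np.array([name_to_idx[n] for n in curve.class_names],
                   np.int16)[cls]
    if breast_mask is not None:
        breast = breast_mask.astype(bool)
        idx[breast] = name_to_idx["adipose"]
        if glandular_mask is not None:
            idx[breast & glandular_mask.astype(bool)] = \
                name_to_idx[ADIPOSE_GLAND_MIX]
    rho = hu_to_density(hu_volume, curve)
    mats = {n: mats[n] for n in names}
    return VoxelPhantom(idx, rho, names, mats, voxel_size, origin, scheme)
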