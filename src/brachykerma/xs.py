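"""Photon interaction coefficients over the Ir-192 energy range.

Per-element mass attenuation and mass energy-absorption coefficients are
bundled as plain-text tables on a 60-point log grid covering 10-1500 keV
(see ``data/elements/``; headers document how they were assembled).
Material tables are built at load time by Bragg additivity — the mixture
coefficient is the mass-fraction-weighted sum of the element coefficients
— and interpolated log-log, the standard choice for photon cross sections.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import OutOfRangeError, ValidationError
from .materials import Material

__all__ = [
    "CrossSectionTable",
    "load_element_tables",
    "build_material_table",
    "lookup_mu",
    "lookup_muen",
    "PROCESSES",
]

PROCESSES = ("photoelectric", "compton", "rayleigh", "total")

_COLS = {"photoelectric": 1, "compton": 2, "rayleigh": 3, "total": 4}

_REL_TOL_SUM = 1e-3


@dataclass(frozen=True)
class CrossSectionTable:
    """Energy grid of interaction coefficients for one material (cm^2/g)."""

    material: str
    energy: np.ndarray          # keV, strictly increasing
    mu_photoelectric: np.ndarray
    mu_compton: np.ndarray
    mu_rayleigh: np.ndarray
    mu_total: np.ndarray
    mu_en: np.ndarray

    def __post_init__(self) -> None:
        e = self.energy
        if not np.all(np.diff(e) > 0):
            raise ValidationError("energy grid must strictly increase")
        for arr, label in ((self.mu_photoelectric, "photoelectric"),
                           (self.mu_compton, "compton"),
                           (self.mu_rayleigh, "rayleigh"),
                           (self.mu_total, "total"),
                           (self.mu_en, "mu_en")):
            if arr.shape != e.shape:
                raise ValidationError(f"{label} grid length mismatch")
            if np.any(arr <= 0):
                raise ValidationError(
                    f"{self.material}: non-positive {label} coefficient")
        s = self.mu_photoelectric + self.mu_compton + self.mu_rayleigh
        if np.any(np.abs(s - self.mu_total) > _REL_TOL_SUM * self.mu_total):
            raise ValidationError(
                f"{self.material}: process components do not sum to total")
        if np.any(self.mu_en > self.mu_total * (1 + 1e-12)):
            raise ValidationError(
                f"{self.material}: mu_en exceeds total attenuation")

    def _column(self, process: str) -> np.ndarray:
        return {"photoelectric": self.mu_photoelectric,
                "compton": self.mu_compton,
                "rayleigh": self.mu_rayleigh,
                "total": self.mu_total,
                "mu_en": self.mu_en}[process]


_ELEMENT_CACHE: dict[str, np.ndarray] | None = None


def load_element_tables() -> dict[str, np.ndarray]:
    """Load the bundled per-element tables.

    Returns a mapping from element symbol to an array with columns
    (energy keV, mu_pe, mu_incoh, mu_coh, mu_total, mu_en), all cm^2/g.
    """
    global _ELEMENT_CACHE
    if _ELEMENT_CACHE is None:
        tables: dict[str, np.ndarray] = {}
        root = resources.files("brachykerma") / "data" / "elements"
        for entry in sorted(root.iterdir(), key=lambda p: p.name):
            if not entry.name.endswith(".txt"):
                continue
            sym = entry.name.split("_", 1)[1].removesuffix(".txt")
            with resources.as_file(entry) as path:
                tables[sym] = np.loadtxt(path)
        if not tables:
            raise ValidationError("no bundled element tables found")
        _ELEMENT_CACHE = tables
    return _ELEMENT_CACHE


def build_material_table(material: Material) -> CrossSectionTable:
    """Assemble a material table by Bragg additivity over its elements."""
    elements = load_element_tables()
    first = next(iter(elements.values()))
    energy = first[:, 0]
    acc = np.zeros((energy.size, 5))
    for sym, w in material.elemental_composition.items():
        if sym not in elements:
            raise ValidationError(
                f"no bundled table for element {sym!r} "
                f"(material {material.name!r})")
        acc += w * elements[sym][:, 1:6]
    return CrossSectionTable(
        material=material.name,
        energy=energy.copy(),
        mu_photoelectric=acc[:, 0],
        mu_compton=acc[:, 1],
        mu_rayleigh=acc[:, 2],
        mu_total=acc[:, 3],
        mu_en=acc[:, 4],
    )


def _loglog_interp(energy, grid: np.ndarray, values: np.ndarray):
    e = np.asarray(energy, float)
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise OutOfRangeError(
            f"energy outside tabulated range [{grid[0]:g}, {grid[-1]:g}] keV")
    out = np.exp(np.interp(np.log(e), np.log(grid), np.log(values)))
    return float(out) if np.isscalar(energy) else out


def lookup_mu(table: CrossSectionTable, energy, process: str = "total"):
    """Mass attenuation coefficient (cm^2/g) at ``energy`` keV.

    Log-log linear interpolation on the table grid; energies outside the
    grid raise :class:`OutOfRangeError` (no extrapolation).
    """
    if process not in PROCESSES:
        raise ValueError(f"unknown process {process!r}; one of {PROCESSES}")
    return _loglog_interp(energy, table.energy, table._column(process))


def lookup_muen(table: CrossSectionTable, energy):
    """Mass energy-absorption coefficient (cm^2/g) at ``energy`` keV."""
    return _loglog_interp(energy, table.energy, table.mu_en)
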