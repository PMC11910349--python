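"""Ir-192 photon source model: emission spectrum, dwell plans, and the
absolute normalization from air-kerma strength to decays.

The source is modelled as a bare point isotropic emitter at each dwell
position: the bundled line spectrum carries the photon energies and
per-decay intensities, and no encapsulation, cable or anisotropy is
modelled.  Absolute dose normalization follows the clinical chain: the
plan's air-kerma strength S_k (U = uGy m^2/h) is converted to a decay rate
through the free-space air-kerma rate per decay computed from the same
spectrum and the bundled air energy-absorption coefficients, so the whole
pipeline is self-consistent with one set of physics data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .errors import InvalidInputError, PlanParseError, ValidationError
from .xs import CrossSectionTable, lookup_muen

__all__ = [
    "PhotonSpectrum",
    "DwellPlan",
    "load_ir192_spectrum",
    "load_dwell_plan",
    "save_dwell_plan",
    "sample_decay",
    "air_kerma_rate_free_space",
    "decays_per_dwell",
]

KEV_TO_J = 1.602176634e-16

#: default clinical prescription: 34 Gy in 10 fractions
DEFAULT_PRESCRIPTION_GY = 34.0
DEFAULT_FRACTIONS = 10
#: default air-kerma strength, a typical fresh 10 Ci HDR source
DEFAULT_SK_U = 40_000.0


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete photon line spectrum: (energy keV, photons per decay)."""

    lines: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValidationError("spectrum has no lines")
        e = self.energies
        i = self.intensities
        if np.any(e <= 10.0) or np.any(e >= 1500.0):
            raise ValidationError("line energies must lie in (10, 1500) keV")
        if np.any(i <= 0):
            raise ValidationError("line intensities must be positive")

    @property
    def energies(self) -> np.ndarray:
        return np.array([l[0] for l in self.lines], float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([l[1] for l in self.lines], float)

    @property
    def total_intensity(self) -> float:
        """Photons emitted per decay."""
        return float(self.intensities.sum())


def load_ir192_spectrum() -> PhotonSpectrum:
    """Load the bundled Ir-192 line spectrum."""
    text = (resources.files("brachykerma") / "data"
            / "ir192_spectrum.txt").read_text()
    lines = []
    for raw in text.splitlines():
        s = raw.split("#", 1)[0].strip()
        if not s:
            continue
        e, i = s.split()
        lines.append((float(e), float(i)))
    spec = PhotonSpectrum(tuple(lines))
    if not 2.0 <= spec.total_intensity <= 2.5:
        raise ValidationError("bundled Ir-192 spectrum intensity out of "
                              "expected [2.0, 2.5] photons/decay")
    return spec


@dataclass(frozen=True)
class DwellPlan:
    """Dwell positions/times with source strength and prescription.

    ``positions`` are (N, 3) mm in patient coordinates; ``times`` (N,) s
    are per-fraction dwell times.  ``air_kerma_strength`` is in U
    (uGy m^2/h), ``prescription_dose`` in Gy for the whole course.
    """

    positions: np.ndarray
    times: np.ndarray
    air_kerma_strength: float = DEFAULT_SK_U
    prescription_dose: float = DEFAULT_PRESCRIPTION_GY
    fractions: int = DEFAULT_FRACTIONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions",
                           np.atleast_2d(np.asarray(self.positions, float)))
        object.__setattr__(self, "times",
                           np.atleast_1d(np.asarray(self.times, float)))
        if self.positions.shape != (self.times.size, 3):
            raise ValidationError("positions must be (N, 3) matching times")
        if self.times.size == 0:
            raise ValidationError("plan has no dwells")
        if np.any(self.times < 0):
            raise ValidationError("negative dwell time")
        if not self.prescription_dose > 0:
            raise ValidationError("prescription must be positive")
        if self.fractions < 1:
            raise ValidationError("fractions must be >= 1")

    @property
    def n_dwells(self) -> int:
        return self.times.size

    def scaled_times(self, factor: float) -> "DwellPlan":
        return replace(self, times=self.times * factor)


_PLAN_KEYS = {"sk_u": "air_kerma_strength",
              "prescription_gy": "prescription_dose",
              "fractions": "fractions"}


def load_dwell_plan(source: str | io.TextIOBase) -> DwellPlan:
    """Parse the structured-text dwell-plan dialect.

    Grammar (one record per line, ``#`` starts a comment)::

        plan      := { record }
        record    := meta | dwell
        meta      := ("sk_u" | "prescription_gy" | "fractions") number
        dwell     := x_mm y_mm z_mm time_s      (four numbers)

    Missing metadata defaults to S_k = 40000 U and 34 Gy in 10 fractions.
    """
    if isinstance(source, str):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    meta: dict[str, float] = {}
    pos, times = [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        s = raw.split("#", 1)[0].strip()
        if not s:
            continue
        parts = s.split()
        if parts[0] in _PLAN_KEYS:
            if len(parts) != 2:
                raise PlanParseError(f"line {lineno}: bad metadata record")
            meta[_PLAN_KEYS[parts[0]]] = float(parts[1])
            continue
        if len(parts) != 4:
            raise PlanParseError(
                f"line {lineno}: expected 'x y z time', got {raw!r}")
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise PlanParseError(f"line {lineno}: {exc}") from exc
        pos.append(vals[:3])
        times.append(vals[3])
    if not times:
        raise PlanParseError("plan contains no dwells")
    kwargs = dict(meta)
    if "fractions" in kwargs:
        kwargs["fractions"] = int(kwargs["fractions"])
    return DwellPlan(np.array(pos), np.array(times), **kwargs)


def save_dwell_plan(plan: DwellPlan, dest: str | io.TextIOBase) -> None:
    """Write a plan in the structured-text dialect (17-digit floats, so a
    write/read round trip is bit-exact)."""
    buf = io.StringIO()
    buf.write(f"sk_u {float(plan.air_kerma_strength)!r}\n")
    buf.write(f"prescription_gy {float(plan.prescription_dose)!r}\n")
    buf.write(f"fractions {plan.fractions}\n")
    for (x, y, z), t in zip(plan.positions, plan.times):
        buf.write(f"{float(x)!r} {float(y)!r} {float(z)!r} "
                  f"{float(t)!r}\n")
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            fh.write(buf.getvalue())
    else:
        dest.write(buf.getvalue())


def sample_decay(spectrum: PhotonSpectrum, rng: np.random.Generator):
    """Draw one emitted photon: line energy (by intensity) and isotropic
    unit direction."""
    p = spectrum.intensities
    e = spectrum.energies[rng.choice(p.size, p=p / p.sum())]
    mu = rng.uniform(-1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(1.0 - mu * mu)
    return float(e), np.array([s * np.cos(phi), s * np.sin(phi), mu])


def air_kerma_rate_free_space(
    spectrum: PhotonSpectrum,
    distance_m: float,
    air_table: CrossSectionTable,
) -> float:
    """Free-space air kerma per decay (Gy) at ``distance_m`` metres.

    Closed form for a point isotropic source in vacuum:
    sum_i I_i E_i (mu_en/rho)_air(E_i) / (4 pi d^2).
    """
    if not distance_m > 0:
        raise InvalidInputError("distance must be positive")
    e = spectrum.energies
    i = spectrum.intensities
    muen = lookup_muen(air_table, e) * 0.1      # cm^2/g -> m^2/kg
    return float(np.sum(i * e * KEV_TO_J * muen)
                 / (4.0 * np.pi * distance_m ** 2))


def decays_per_dwell(
    plan: DwellPlan,
    spectrum: PhotonSpectrum,
    air_table: CrossSectionTable,
) -> np.ndarray:
    """Number of decays during each dwell (one fraction).

    The plan's air-kerma strength (uGy m^2/h) divided by the free-space
    air-kerma rate at 1 m per unit decay rate gives the source decay rate;
    multiplied by each dwell time it gives per-dwell decays, the weights
    used to allocate histories and to convert per-decay dose to Gy.
    """
    if not plan.air_kerma_strength > 0:
        raise ValidationError("plan air-kerma strength must be positive")
    gy_per_decay_1m = air_kerma_rate_free_space(spectrum, 1.0, air_table)
    # U per (decay/s): Gy/decay * 1e6 uGy/Gy * 3600 s/h, at d = 1 m
    u_per_decay_rate = gy_per_decay_1m * 1e6 * 3600.0
    decay_rate = plan.air_kerma_strength / u_per_decay_rate   # decays/s
    return decay_rate * plan.times
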