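"""Fuoss ion-pair dissociation model and the ion-pairing correction.

In a solvent of low relative permittivity (for 1,2-difluorobenzene
epsilon_r = 13.4) deprotonation of an acid HA by a base B yields the ion
pair BH+A- rather than free ions, so relative spectrophotometric
measurements deliver differences of *ion-pair* acidities (Delta pK_ip).
The Fuoss sphere-in-continuum model supplies the ion-pair dissociation
constant K_d of each salt from the interionic distance ``a``, the
permittivity and the temperature,

    K_d = 3000 e^b / (4 pi N a^3),    b = -q^2 / (a eps_r k T)

with the constants written in CGS units (q in cm^3/2 g^1/2 s^-1, k in
cm^2 g s^-2 K^-1, a in cm).  The difference of the pK_d values of the
two salts of an acid pair converts Delta pK_ip into the free-ion
Delta pK_a:

    Delta pK_a = Delta pK_ip + Delta pK_d.

Public interfaces take radii in angstroms and temperatures in kelvin;
the CGS evaluation is internal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "IonRadius",
    "FuossEnvironment",
    "mean_radius",
    "fuoss_b",
    "fuoss_kd",
    "fuoss_pkd",
    "delta_pkd",
    "correct_to_pka",
]

ANGSTROM_CM = 1e-8

#: CGS values of the physical constants as conventionally used with the
#: Fuoss equation (elementary charge, Boltzmann constant, Avogadro number).
Q_CGS = 4.80e-10
K_CGS = 1.38e-16
N_AVOGADRO = 6.02e23


@dataclass(frozen=True)
class FuossEnvironment:
    """Solvent/temperature context for Fuoss-model evaluations.

    Defaults are those of 1,2-difluorobenzene at the acidity-measurement
    temperature (24.1 C).
    """

    epsilon_r: float = 13.4
    temperature: float = 297.25  # K
    q: float = Q_CGS
    k: float = K_CGS
    N: float = N_AVOGADRO

    def __post_init__(self) -> None:
        if not self.epsilon_r > 1:
            raise ValueError(f"epsilon_r must exceed 1, got {self.epsilon_r}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def coulomb_constant_cm(self) -> float:
        """C = q^2 log10(e) / (eps_r k T), in cm (the ``C`` of the
        Delta pK_d expression)."""
        return self.q**2 * math.log10(math.e) / (self.epsilon_r * self.k * self.temperature)


@dataclass(frozen=True)
class IonRadius:
    """Ionic radius of one species, by up to three estimators (angstrom).

    ``r_sphere`` comes from the molecular volume via the sphere formula,
    ``r_cuboid`` from the bounding-cuboid dimensions, ``r_surface`` from the
    mean distance of molecular-surface segments from the centroid.  The
    working radius is the arithmetic mean of whichever are available.
    """

    species: str
    r_sphere: Optional[float] = None
    r_cuboid: Optional[float] = None
    r_surface: Optional[float] = None
    charge: int = -1

    def __post_init__(self) -> None:
        comps = self._components()
        if not comps:
            raise ValueError(f"{self.species}: at least one radius estimate is required")
        if any(r <= 0 for r in comps):
            raise ValueError(f"{self.species}: radii must be positive, got {comps}")

    def _components(self) -> list[float]:
        return [r for r in (self.r_sphere, self.r_cuboid, self.r_surface) if r is not None]

    @property
    def r_mean(self) -> float:
        comps = self._components()
        if len(comps) < 3:
            warnings.warn(
                f"{self.species}: only {len(comps)} of 3 radius estimates present; "
                "using the mean of the available ones",
                stacklevel=2,
            )
        return sum(comps) / len(comps)


def mean_radius(
    species: str,
    r_sphere: Optional[float] = None,
    r_cuboid: Optional[float] = None,
    r_surface: Optional[float] = None,
    charge: int = -1,
) -> IonRadius:
    """Build an :class:`IonRadius` from the available estimators."""
    return IonRadius(species, r_sphere, r_cuboid, r_surface, charge)


def fuoss_b(a_cm: float, env: FuossEnvironment = FuossEnvironment()) -> float:
    """Bjerrum-type exponent b = -q^2/(a eps_r k T); negative for a > 0."""
    if a_cm <= 0:
        raise ValueError(f"interion distance must be positive, got {a_cm} cm")
    return -env.q**2 / (a_cm * env.epsilon_r * env.k * env.temperature)


def fuoss_kd(a_cm: float, env: FuossEnvironment = FuossEnvironment()) -> float:
    """Fuoss ion-pair dissociation constant K_d (mol L^-1) at interion
    distance ``a_cm`` (cm)."""
    b = fuoss_b(a_cm, env)
    return 3000.0 * math.exp(b) / (4.0 * math.pi * env.N * a_cm**3)


def fuoss_pkd(a_cm: float, env: FuossEnvironment = FuossEnvironment()) -> float:
    """pK_d = -log10 K_d, evaluated in the rearranged logarithmic form

        pK_d = -log10(3000/(4 pi N)) + (q^2 log10 e / (eps_r k T)) / a
               + 3 log10 a

    which is algebraically identical to -log10 of :func:`fuoss_kd`.
    """
    if a_cm <= 0:
        raise ValueError(f"interion distance must be positive, got {a_cm} cm")
    const = -math.log10(3000.0 / (4.0 * math.pi * env.N))
    return const + env.coulomb_constant_cm / a_cm + 3.0 * math.log10(a_cm)


def fuoss_pkd_angstrom(a_angstrom: float, env: FuossEnvironment = FuossEnvironment()) -> float:
    """Convenience wrapper of :func:`fuoss_pkd` taking ``a`` in angstroms."""
    return fuoss_pkd(a_angstrom * ANGSTROM_CM, env)


def delta_pkd(
    r_a1: IonRadius,
    r_a2: IonRadius,
    r_b: IonRadius,
    env: FuossEnvironment = FuossEnvironment(),
) -> float:
    """Delta pK_d = pK_d(BH+A2-) - pK_d(BH+A1-) of an acid pair sharing the
    counterion B+.

    Equals C (1/(r_A2 + r_B) - 1/(r_A1 + r_B)) + 3 log10((r_A2+r_B)/(r_A1+r_B))
    with C in length units; radii enter as the mean of the available
    estimators.
    """
    a1 = (r_a1.r_mean + r_b.r_mean) * ANGSTROM_CM
    a2 = (r_a2.r_mean + r_b.r_mean) * ANGSTROM_CM
    if a1 <= 0 or a2 <= 0:
        raise ValueError("interion distances must be positive")
    c = env.coulomb_constant_cm
    return c * (1.0 / a2 - 1.0 / a1) + 3.0 * math.log10(a2 / a1)


#: Soft plausibility bound on the magnitude of the ion-pairing correction for
#: realistic radii; larger values are reported with a warning, not rejected.
DPKD_SOFT_LIMIT = 0.2


@dataclass
class CorrectedPair:
    """A pairwise acidity difference after the ion-pairing correction."""

    acid1: str
    acid2: str
    delta_pkip: float
    delta_pkd: float
    counterion: str = "tBuP1(pyrr)3-H+"

    @property
    def delta_pka(self) -> float:
        return self.delta_pkip + self.delta_pkd


def correct_to_pka(pair, dpkd: float, counterion: str = "tBuP1(pyrr)3-H+") -> CorrectedPair:
    """Apply Delta pK_a = Delta pK_ip + Delta pK_d to one measured pair.

    ``pair`` is any object with ``acid1``, ``acid2`` and ``delta_pkip``
    attributes (e.g. :class:`acidscale.spectra.PairResult`).
    """
    if not math.isfinite(pair.delta_pkip) or not math.isfinite(dpkd):
        raise ValueError("delta_pkip and delta_pkd must be finite")
    if abs(dpkd) > DPKD_SOFT_LIMIT:
        warnings.warn(
            f"|Delta pK_d| = {abs(dpkd):.3f} exceeds the {DPKD_SOFT_LIMIT} units expected "
            "for realistic ion sizes; check the radii",
            stacklevel=2,
        )
    return CorrectedPair(pair.acid1, pair.acid2, pair.delta_pkip, dpkd, counterion)
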