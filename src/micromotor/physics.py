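"""Thermal physics of a micron-sized sphere in a viscous solvent.

Stokes-Einstein translational and rotational diffusion coefficients, the
rotational diffusion time that bounds the propulsive fitting window, and the
closed-form mean-squared displacement of an active Brownian particle (ABP).

Units: positions in micrometres, time in seconds, temperature in kelvin,
viscosity in kg m^-1 s^-1 (Pa s). Diffusion coefficients are returned in
um^2 s^-1 (translational) and s^-1 (rotational).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BOLTZMANN_J_PER_K",
    "ThermalParams",
    "RotationalScale",
    "translational_diffusion",
    "rotational_diffusion",
    "rotational_time",
    "abp_msd_theory",
]

#: Boltzmann constant, J K^-1 (2019 SI exact value).
BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class ThermalParams:
    """Sphere radius and solvent state entering the Stokes-Einstein relations.

    Defaults describe a 1.00 um-radius silica microsphere in water-like
    solvent at 24 degC (297.15 K), viscosity 0.9107e-3 kg m^-1 s^-1.

    Attributes
    ----------
    radius_um : float
        Particle radius in micrometres.
    temperature_K : float
        Absolute temperature in kelvin.
    viscosity_Pa_s : float
        Dynamic viscosity of the solvent in kg m^-1 s^-1.
    boltzmann_J_per_K : float
        Boltzmann constant; fixed, exposed for unit transparency.
    """

    radius_um: float = 1.00
    temperature_K: float = 297.15
    viscosity_Pa_s: float = 0.9107e-3
    boltzmann_J_per_K: float = field(default=BOLTZMANN_J_PER_K)

    def __post_init__(self) -> None:
        for name in ("radius_um", "temperature_K", "viscosity_Pa_s", "boltzmann_J_per_K"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")


def translational_diffusion(tp: ThermalParams) -> float:
    """Stokes-Einstein translational diffusion coefficient, um^2 s^-1.

    D_t = k_B T / (6 pi eta r) for a sphere of radius r.
    """
    r_m = tp.radius_um * 1e-6
    d_m2_s = tp.boltzmann_J_per_K * tp.temperature_K / (6.0 * math.pi * tp.viscosity_Pa_s * r_m)
    return d_m2_s * 1e12  # m^2 -> um^2


def rotational_diffusion(tp: ThermalParams) -> float:
    """Stokes-Einstein rotational diffusion coefficient, s^-1.

    D_r = k_B T / (8 pi eta r^3). At the default parameters this evaluates
    to 0.1792 s^-1 for a 1.00 um-radius sphere.
    """
    r_m = tp.radius_um * 1e-6
    return tp.boltzmann_J_per_K * tp.temperature_K / (8.0 * math.pi * tp.viscosity_Pa_s * r_m**3)


def rotational_time(d_r: float) -> float:
    """Rotational diffusion time tau_r = 1 / D_r, seconds.

    tau_r is the timescale over which the particle heading decorrelates;
    the propulsive parabola MSD = 4 D_t t + v^2 t^2 is valid only for
    t << tau_r.
    """
    if not np.isfinite(d_r) or d_r <= 0:
        raise ValueError(f"D_r must be finite and > 0, got {d_r!r}")
    return 1.0 / d_r


@dataclass(frozen=True)
class RotationalScale:
    """Rotational diffusion coefficient D_r (s^-1) and time tau_r = 1/D_r (s)."""

    d_r: float
    tau_r: float

    def __post_init__(self) -> None:
        if self.d_r <= 0 or self.tau_r <= 0:
            raise ValueError("D_r and tau_r must be > 0")
        if abs(self.d_r * self.tau_r - 1.0) > 1e-12:
            raise ValueError("tau_r must equal 1/D_r")

    @classmethod
    def from_thermal(cls, tp: ThermalParams) -> "RotationalScale":
        d_r = rotational_diffusion(tp)
        return cls(d_r=d_r, tau_r=rotational_time(d_r))


def abp_msd_theory(t, v: float, d_t: float, d_r: float):
    """Exact ensemble MSD of a 2-D active Brownian particle.

    MSD(t) = 4 D_t t + (2 v^2 / D_r^2) * (D_r t + exp(-D_r t) - 1)

    which reduces to 4 D_t t + v^2 t^2 for t << tau_r (propulsive regime)
    and to (4 D_t + 2 v^2 / D_r) t for t >> tau_r (enhanced diffusion).

    Parameters
    ----------
    t : array_like
        Lag times, s.
    v : float
        Propulsion speed, um s^-1.
    d_t : float
        Translational diffusion coefficient, um^2 s^-1.
    d_r : float
        Rotational diffusion coefficient, s^-1. ``d_r == 0`` gives the
        ballistic limit 4 D_t t + v^2 t^2 exactly.
    """
    t = np.asarray(t, dtype=float)
    if v < 0 or d_t < 0 or d_r < 0:
        raise ValueError("v, D_t and D_r must be >= 0")
    if d_r == 0:
        return 4.0 * d_t * t + v**2 * t**2
    x = d_r * t
    # expm1 keeps precision for small D_r t where the bracket is O(x^2)
    bracket = x + np.expm1(-x)
    return 4.0 * d_t * t + 2.0 * v**2 / d_r**2 * bracket
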