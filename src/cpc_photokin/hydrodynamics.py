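"""Turbulent pipe-flow model for the CPC tubes.

The reactor operates in the fully developed turbulent regime
(Re ~ 1.9e4 at 30.2 L/min in a 33 mm tube).  The axial velocity profile is
the classical power law ``v_z = v_max * (1 - r/R)^(1/n)`` whose exponent is
obtained from the Darcy friction factor via the log-law relation
``n = 0.41 * sqrt(8/f)``; at the operating Reynolds number this recovers the
canonical one-seventh profile (n ~ 7.1, v_max/v_avg ~ 1.22).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlowSpec",
    "reynolds_number",
    "friction_factor",
    "power_law_exponent",
    "velocity_ratio",
    "velocity_profile",
]

_LAMINAR_RE = 2300.0


def reynolds_number(q: float, diameter: float, kinematic_viscosity: float) -> float:
    """Reynolds number ``Re = 4 Q / (pi D nu)`` for volumetric flow ``q`` (m^3/s)."""
    if q <= 0 or diameter <= 0 or kinematic_viscosity <= 0:
        raise ValueError("q, diameter and kinematic_viscosity must be positive")
    return 4.0 * q / (math.pi * diameter * kinematic_viscosity)


def friction_factor(re: float) -> float:
    """Darcy friction factor from the Blasius correlation ``f = 0.316 Re^-0.25``.

    Valid for 4e3 < Re < 1e5; outside that range a warning is emitted and the
    extrapolated value is still returned.
    """
    if re <= 0:
        raise ValueError("Re must be positive")
    if not 4.0e3 < re < 1.0e5:
        warnings.warn(
            f"Blasius correlation used outside its validity range (Re={re:.3g})",
            stacklevel=2,
        )
    return 0.316 * re**-0.25


def power_law_exponent(f: float) -> float:
    """Power-law exponent ``n = 0.41 * sqrt(8/f)`` from the Darcy friction factor."""
    if f <= 0:
        raise ValueError("friction factor must be positive")
    return 0.41 * math.sqrt(8.0 / f)


def velocity_ratio(n: float) -> float:
    """``v_max / v_avg = (n+1)(2n+1) / (2 n^2)`` for the power-law profile."""
    if n <= 0:
        raise ValueError("n must be positive")
    return (n + 1.0) * (2.0 * n + 1.0) / (2.0 * n**2)


def velocity_profile(r, tube_radius: float, n: float, v_max: float):
    """Axial velocity ``v_z(r) = v_max (1 - r/R)^(1/n)``, m/s.

    Vanishes at the wall and equals ``v_max`` on the axis.  ``r`` may be a
    scalar or array in ``[0, R]``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > tube_radius * (1 + 1e-12)):
        raise ValueError("r must lie within [0, R]")
    x = np.clip(1.0 - r / tube_radius, 0.0, 1.0)
    out = v_max * x ** (1.0 / n)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FlowSpec:
    """Flow conditions and derived turbulent-profile parameters."""

    q: float  #: volumetric flow, m^3/s
    diameter: float  #: tube inner diameter used for Re, m
    kinematic_viscosity: float = 1.0e-6  #: m^2/s (water, ~20 C)
    reynolds: float = 0.0
    darcy_f: float = 0.0
    n_exponent: float = 0.0
    v_avg: float = 0.0
    v_max: float = 0.0
    laminar: bool = False

    @classmethod
    def from_conditions(
        cls, q: float, diameter: float, kinematic_viscosity: float = 1.0e-6
    ) -> "FlowSpec":
        re = reynolds_number(q, diameter, kinematic_viscosity)
        f = friction_factor(re)
        n = power_law_exponent(f)
        v_avg = q / (math.pi * (diameter / 2.0) ** 2)
        return cls(
            q=q,
            diameter=diameter,
            kinematic_viscosity=kinematic_viscosity,
            reynolds=re,
            darcy_f=f,
            n_exponent=n,
            v_avg=v_avg,
            v_max=v_avg * velocity_ratio(n),
            laminar=re < _LAMINAR_RE,
        )

    def profile(self, r):
        """Axial velocity at radius ``r`` (m), m/s."""
        return velocity_profile(r, self.diameter / 2.0, self.n_exponent, self.v_max)
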