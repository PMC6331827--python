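"""Six-flux absorption-scattering model (SFM) for a TiO2 slurry slab.

The SFM tracks scattered photons along the six Cartesian directions and
collapses the radiative transfer equation into a closed-form, one-dimensional
absorption profile.  Given the spectrum-averaged optical properties of the
catalyst suspension (absorption coefficient ``kappa``, scattering coefficient
``sigma`` and the forward/backward/side scattering probabilities of the phase
function), it yields the local volumetric rate of photon absorption (LVRPA,
W/m^3) at any depth into an illuminated slab of slurry.

The chain of derived quantities is::

    omega      = sigma / (sigma + kappa)              scattering albedo
    a, b       combination coefficients of the six-flux phase function
    omega_corr = b / a                                corrected albedo
    tau        = (sigma + kappa) * delta * C_cat      optical thickness
    tau_app    = a * tau * sqrt(1 - omega_corr^2)     apparent optical thickness
    gamma      slab back-reflection coefficient
    lambda     photon absorption-scattering mean path

and the LVRPA profile is a combination of decaying/growing exponentials on
the scale ``lambda``.  The model is formally identical to a two-flux
(Kubelka-Munk) slab with effective albedo ``omega_corr`` and attenuation rate
``1/lambda``; that equivalence is used for the slab reflectance and
transmittance helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalProperties",
    "SFMDerived",
    "SlurryState",
    "aeroxide_p25",
    "scattering_albedo",
    "sfm_ab_coefficients",
    "corrected_albedo",
    "optical_thickness",
    "apparent_optical_thickness",
    "gamma_coefficient",
    "photon_path_length",
    "derive_sfm",
    "lvrpa_slab",
    "slab_reflectance_transmittance",
]

#: below this corrected albedo the closed form degenerates to 0/0 and the
#: analytic Beer-Lambert limit is evaluated instead
_OMEGA_CORR_EPS = 1e-8

_PROB_TOL = 1e-6


@dataclass(frozen=True)
class OpticalProperties:
    """Spectrum-averaged optical properties of a catalyst slurry.

    Parameters
    ----------
    kappa : float
        Absorption coefficient, m^2/kg.
    sigma : float
        Scattering coefficient, m^2/kg.
    p_f, p_b, p_s : float
        Forward, backward and side scattering probabilities of the six-flux
        phase function.  One forward, one backward and four side directions,
        so ``p_f + p_b + 4*p_s == 1``.
    """

    kappa: float
    sigma: float
    p_f: float
    p_b: float
    p_s: float

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.sigma < 0:
            raise ValueError("kappa and sigma must be non-negative")
        if self.kappa + self.sigma <= 0:
            raise ValueError("total extinction kappa + sigma must be positive")
        if min(self.p_f, self.p_b, self.p_s) < 0:
            raise ValueError("scattering probabilities must be non-negative")
        total = self.p_f + self.p_b + 4.0 * self.p_s
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(
                f"p_f + p_b + 4*p_s must equal 1 (got {total!r}); "
                "the six-flux phase function has 1 forward, 1 backward and "
                "4 side directions"
            )

    @property
    def beta(self) -> float:
        """Extinction coefficient ``kappa + sigma``, m^2/kg."""
        return self.kappa + self.sigma


def aeroxide_p25() -> OpticalProperties:
    """Optical properties of TiO2 Aeroxide P-25 in water, averaged over the
    solar spectrum up to the TiO2 absorption edge (385 nm)."""
    return OpticalProperties(kappa=174.7, sigma=1295.8, p_f=0.110, p_b=0.710, p_s=0.045)


@dataclass(frozen=True)
class SlurryState:
    """A catalyst slurry together with the optical path it occupies."""

    props: OpticalProperties
    c_cat: float  #: catalyst concentration, kg/m^3 (== g/L)
    delta: float  #: optical path length of the slab, m

    def __post_init__(self) -> None:
        if self.c_cat < 0:
            raise ValueError("c_cat must be non-negative")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass(frozen=True)
class SFMDerived:
    """Derived six-flux quantities for a given slurry and path length."""

    omega: float
    a_coef: float
    b_coef: float
    omega_corr: float
    tau: float
    tau_app: float
    gamma: float
    lambda_omega: float  #: photon absorption-scattering length, m


def scattering_albedo(props: OpticalProperties) -> float:
    """Scattering albedo ``omega = sigma / (sigma + kappa)``."""
    if props.beta <= 0:
        raise ValueError("scattering albedo undefined for zero total extinction")
    return props.sigma / props.beta


def sfm_ab_coefficients(props: OpticalProperties, omega: float) -> tuple[float, float]:
    """Six-flux combination coefficients ``(a, b)``.

    ``a = 1 - omega*p_f - 4*omega^2*p_s^2 / D`` and
    ``b = omega*p_b + 4*omega^2*p_s^2 / D`` with
    ``D = 1 - omega*p_f - omega*p_b - 2*omega*p_s``.
    """
    den = 1.0 - omega * props.p_f - omega * props.p_b - 2.0 * omega * props.p_s
    if den <= 0:
        raise ValueError(
            "invalid phase-function probabilities: the six-flux denominator "
            f"1 - w*p_f - w*p_b - 2*w*p_s = {den!r} is not positive"
        )
    side = 4.0 * omega**2 * props.p_s**2 / den
    a = 1.0 - omega * props.p_f - side
    b = omega * props.p_b + side
    return a, b


def corrected_albedo(a: float, b: float) -> float:
    """Corrected scattering albedo ``omega_corr = b / a``."""
    if a <= 0:
        raise ValueError("coefficient a must be positive")
    return b / a


def optical_thickness(slurry: SlurryState) -> float:
    """Optical thickness ``tau = (sigma + kappa) * delta * C_cat``."""
    return slurry.props.beta * slurry.delta * slurry.c_cat


def apparent_optical_thickness(a: float, tau: float, omega_corr: float) -> float:
    """Apparent optical thickness ``tau_app = a * tau * sqrt(1 - omega_corr^2)``."""
    if not 0.0 <= omega_corr < 1.0:
        raise ValueError("omega_corr must be in [0, 1)")
    return a * tau * math.sqrt(1.0 - omega_corr**2)


def gamma_coefficient(omega_corr: float, tau_app: float) -> float:
    """Slab back-reflection coefficient.

    ``gamma = (1 - sqrt(1-w^2)) / (1 + sqrt(1-w^2)) * exp(-2*tau_app)`` with
    ``w = omega_corr``; it vanishes in the optically thick limit.
    """
    if not 0.0 <= omega_corr < 1.0:
        raise ValueError("omega_corr must be in [0, 1)")
    if tau_app < 0:
        raise ValueError("tau_app must be non-negative")
    root = math.sqrt(1.0 - omega_corr**2)
    return (1.0 - root) / (1.0 + root) * math.exp(-2.0 * tau_app)


def photon_path_length(
    a: float, props: OpticalProperties, c_cat: float, omega_corr: float
) -> float:
    """Photon absorption-scattering length, m.

    ``lambda = 1 / (a * (sigma+kappa) * C_cat * sqrt(1 - omega_corr^2))``;
    it halves when the catalyst load doubles.
    """
    if c_cat <= 0:
        raise ValueError("photon path length is infinite for c_cat == 0")
    if not 0.0 <= omega_corr < 1.0:
        raise ValueError("omega_corr must be in [0, 1)")
    return 1.0 / (a * props.beta * c_cat * math.sqrt(1.0 - omega_corr**2))


def derive_sfm(slurry: SlurryState) -> SFMDerived:
    """Evaluate the full chain of derived six-flux quantities for a slurry."""
    props = slurry.props
    omega = scattering_albedo(props)
    a, b = sfm_ab_coefficients(props, omega)
    omega_corr = corrected_albedo(a, b)
    tau = optical_thickness(slurry)
    tau_app = apparent_optical_thickness(a, tau, omega_corr)
    gamma = gamma_coefficient(omega_corr, tau_app)
    if slurry.c_cat > 0 and omega_corr < 1.0:
        lam = photon_path_length(a, props, slurry.c_cat, omega_corr)
    else:
        lam = math.inf
    return SFMDerived(
        omega=omega,
        a_coef=a,
        b_coef=b,
        omega_corr=omega_corr,
        tau=tau,
        tau_app=tau_app,
        gamma=gamma,
        lambda_omega=lam,
    )


def lvrpa_slab(rp, i0: float, sfm: SFMDerived, slurry: SlurryState):
    """LVRPA (W/m^3) at depth ``rp`` (m) into a slab of slurry.

    The closed-form six-flux profile is::

        LVRPA = I0 / (lam * w * (1 - gamma)) *
                [ (w - 1 + s) * exp(-rp/lam) + gamma * (w - 1 - s) * exp(rp/lam) ]

    with ``w = omega_corr`` and ``s = sqrt(1 - w^2)``.  For a vanishing
    corrected albedo the expression is a 0/0 form and the analytic
    Beer-Lambert limit ``I0 * kappa * C * exp(-kappa*C*rp)`` is returned.

    ``rp`` may be a scalar or an array; values must lie in ``[0, delta]``.
    """
    rp = np.asarray(rp, dtype=float)
    if np.any(rp < -1e-12) or np.any(rp > slurry.delta * (1 + 1e-12)):
        raise ValueError("rp must lie within [0, delta]")
    if sfm.gamma >= 1.0:
        raise ValueError("gamma must be < 1")
    if slurry.c_cat == 0:
        return np.zeros_like(rp)
    w = sfm.omega_corr
    if w < _OMEGA_CORR_EPS:
        kc = slurry.props.kappa * slurry.c_cat
        return i0 * kc * np.exp(-kc * rp)
    s = math.sqrt(1.0 - w**2)
    lam = sfm.lambda_omega
    pref = i0 / (lam * w * (1.0 - sfm.gamma))
    out = pref * (
        (w - 1.0 + s) * np.exp(-rp / lam)
        + sfm.gamma * (w - 1.0 - s) * np.exp(rp / lam)
    )
    return out


def slab_reflectance_transmittance(sfm: SFMDerived) -> tuple[float, float]:
    """Diffuse reflectance and transmittance of the finite six-flux slab.

    Uses the two-flux equivalence of the SFM: attenuation rate ``1/lambda``
    and semi-infinite reflectance ``R_inf = (1 - sqrt(1-w^2)) / w``.  Energy
    closure ``A = 1 - R - T`` equals the integral of the LVRPA profile over
    the slab to quadrature accuracy.
    """
    w = sfm.omega_corr
    if w < _OMEGA_CORR_EPS:
        t = math.exp(-sfm.tau)
        return 0.0, t
    s = math.sqrt(1.0 - w**2)
    r_inf = (1.0 - s) / w
    e = math.exp(-2.0 * sfm.tau_app)
    denom = 1.0 - r_inf**2 * e
    refl = r_inf * (1.0 - e) / denom
    trans = (1.0 - r_inf**2) * math.exp(-sfm.tau_app) / denom
    return refl, trans
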