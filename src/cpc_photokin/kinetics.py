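"""Modified Langmuir-Hinshelwood photocatalytic kinetics and estimation.

The TOC mineralisation rate is described by a Langmuir-Hinshelwood law with
saturable surface coverage, scaled by the rate of photon absorption raised
to an exponent ``m`` (0.5 when charge-carrier recombination dominates at
high irradiance, which is the default):

    r_TOC = -k_T * K_R * [TOC] / (1 + K_R * [TOC]) * (photon term)^m

Two photon-term conventions are supported and must not be mixed silently:

``lumped``
    The fit convention: the whole-reactor VRPA (W) enters as ``VRPA^m`` and
    the rate is a tank-scale quantity ``V_T * d[TOC]/dt30W`` (ppm m^3/s);
    ``k_T`` then carries units ppm m^3 s^-1 W^-m.

``local``
    The reactor-marching convention: the local LVRPA (W/m^3) enters per
    streamline; ``k_T`` carries units ppm m^(3m) s^-1 W^-m
    (ppm m^1.5 s^-1 W^-0.5 for m=0.5).

The two constants differ by the geometry factor
``G = Int(LVRPA^m dV) / VRPA^m`` of the radiation field (see
:func:`cpc_photokin.reactor.geometry_factor`).

Estimation follows the classical initial-rate linearisation: plotting
``1/(V_T |d[TOC]/dt|)`` against ``1/[TOC]0`` gives a line with
``slope = 1/(K_R k_T VRPA^m)`` and ``intercept = 1/(k_T VRPA^m)``, so
``K_R = intercept/slope`` and ``k_T = 1/(intercept * VRPA^m)``.

Time axes are standardised to ``t30W``, the equivalent illumination time at
the reference clear-sky UV irradiance of 30 W/m^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "KineticParameters",
    "TOCTimeSeries",
    "LHFit",
    "lh_rate",
    "initial_rate",
    "fit_lh_linearized",
    "t30w_axis",
    "uva_from_uvb",
    "T30W_REFERENCE_IRRADIANCE",
]

#: reference clear-sky UV irradiance for the t30W axis, W/m^2
T30W_REFERENCE_IRRADIANCE = 30.0

#: UV-B share of the total UV A+B solar irradiance
UVB_FRACTION_OF_UVAB = 0.10


@dataclass(frozen=True)
class KineticParameters:
    """Modified L-H constants.

    ``k_t`` units depend on the photon-term convention (module docstring);
    ``k_r`` is the apparent adsorption constant under irradiation (1/ppm),
    distinct from (and not constrained to equal) the dark ``K_ads``.
    """

    k_t: float
    k_r: float
    m_exp: float = 0.5

    def __post_init__(self) -> None:
        if self.k_t <= 0 or self.k_r <= 0:
            raise ValueError("k_t and k_r must be positive")
        if not 0.5 <= self.m_exp <= 1.0:
            raise ValueError("m must lie in [0.5, 1.0]")


@dataclass
class TOCTimeSeries:
    """A TOC trajectory on the standardized t30W axis."""

    t30w_min: np.ndarray
    toc_ppm: np.ndarray
    estrogens_ppm: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t30w_min = np.asarray(self.t30w_min, dtype=float)
        self.toc_ppm = np.asarray(self.toc_ppm, dtype=float)
        if self.t30w_min.shape != self.toc_ppm.shape:
            raise ValueError("t30w_min and toc_ppm must have the same shape")
        if len(self.t30w_min) and abs(self.t30w_min[0]) > 1e-9:
            raise ValueError("time axis must start at 0")
        if np.any(np.diff(self.t30w_min) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any(self.toc_ppm <= 0):
            raise ValueError("toc_ppm must be positive")
        if self.estrogens_ppm is not None:
            self.estrogens_ppm = np.asarray(self.estrogens_ppm, dtype=float)

    def __len__(self) -> int:
        return len(self.t30w_min)


def lh_rate(toc, params: KineticParameters, photon_term: float):
    """L-H rate ``-k_T*K_R*[TOC]/(1+K_R*[TOC]) * photon_term`` (signed, <= 0).

    ``photon_term`` is the photon-absorption quantity already raised to the
    exponent ``m`` (e.g. ``VRPA**m`` in the lumped convention).
    """
    if photon_term < 0:
        raise ValueError("photon term must be non-negative")
    toc = np.asarray(toc, dtype=float)
    if np.any(toc < 0):
        raise ValueError("toc must be non-negative")
    out = -params.k_t * params.k_r * toc / (1.0 + params.k_r * toc) * photon_term
    return out if out.ndim else float(out)


def initial_rate(series: TOCTimeSeries, window: int = 3) -> tuple[float, float]:
    """Initial TOC removal rate (ppm/min) and its standard error.

    OLS slope through the first ``window`` points of the trajectory;
    negative for a decaying series.
    """
    if window < 2:
        raise ValueError("window must be at least 2 points")
    if len(series) < window:
        raise ValueError(f"series has {len(series)} points, window needs {window}")
    t = series.t30w_min[:window]
    c = series.toc_ppm[:window]
    if window == 2:
        slope = (c[1] - c[0]) / (t[1] - t[0])
        return float(slope), float("nan")
    res = stats.linregress(t, c)
    return float(res.slope), float(res.stderr)


@dataclass
class LHFit:
    """Linearised L-H fit result."""

    params: KineticParameters | None
    slope: float
    intercept: float
    r_squared: float
    vrpa: float
    m_exp: float
    success: bool
    message: str = ""


def fit_lh_linearized(
    initial_rates,
    vrpa: float,
    m_exp: float = 0.5,
) -> LHFit:
    """Estimate ``(k_T, K_R)`` from initial rates at several starting TOCs.

    Parameters
    ----------
    initial_rates : sequence of (toc0_ppm, rate)
        ``rate`` is the tank-scale initial removal rate ``V_T*|d[TOC]/dt30W|``
        in ppm m^3/s (signed rates are accepted and their magnitude used).
    vrpa : float
        Whole-reactor volumetric rate of photon absorption, W.
    m_exp : float
        Photon-order exponent.

    Returns ``k_T = 1/(intercept * VRPA^m)`` in the lumped convention and
    ``K_R = intercept/slope``; a non-positive slope or intercept is returned
    as a flagged failure.
    """
    pts = [(float(c0), abs(float(r))) for c0, r in initial_rates]
    if len({c0 for c0, _ in pts}) < 2:
        raise ValueError("need at least 2 distinct initial concentrations")
    if any(r == 0 for _, r in pts):
        raise ValueError("zero initial rate cannot be inverted")
    x = np.array([1.0 / c0 for c0, _ in pts])
    y = np.array([1.0 / r for _, r in pts])
    if len(pts) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    if slope <= 0 or intercept <= 0:
        return LHFit(None, slope, intercept, r2, vrpa, m_exp, False,
                     "non-positive slope or intercept")
    k_r = intercept / slope
    k_t = 1.0 / (intercept * vrpa**m_exp)
    return LHFit(
        params=KineticParameters(k_t=k_t, k_r=k_r, m_exp=m_exp),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        vrpa=vrpa,
        m_exp=m_exp,
        success=True,
    )


def t30w_axis(clock_min, uv_irradiance, v_irr: float, v_t: float):
    """Standardised illumination time, min.

    Cumulative ``t30W(n) = t30W(n-1) + dt * (I_UV/30) * (V_irr/V_T)``: clock
    intervals are weighted by the measured UV irradiance relative to the
    30 W/m^2 clear-sky reference and by the irradiated volume fraction.
    ``uv_irradiance`` is evaluated on the intervals using the left endpoint.
    """
    t = np.asarray(clock_min, dtype=float)
    irr = np.broadcast_to(np.asarray(uv_irradiance, dtype=float), t.shape)
    if np.any(irr < 0):
        raise ValueError("irradiance must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("clock times must be strictly increasing")
    out = np.zeros_like(t)
    dt = np.diff(t)
    out[1:] = np.cumsum(dt * irr[:-1] / T30W_REFERENCE_IRRADIANCE) * (v_irr / v_t)
    return out


def uva_from_uvb(i_uvb: float) -> float:
    """Total UV A+B irradiance from a UV-B reading (UV-B is ~10% of UV A+B)."""
    if i_uvb < 0:
        raise ValueError("irradiance must be non-negative")
    return i_uvb / UVB_FRACTION_OF_UVAB
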