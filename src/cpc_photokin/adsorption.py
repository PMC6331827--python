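"""Langmuir adsorption isotherm and dark-adsorption parameter estimation.

The estrogen formulation's adsorption on the TiO2 surface is tracked through
the total organic carbon (TOC) and described by a monolayer Langmuir
isotherm

    q = q0 * K_ads * [TOC] / (1 + K_ads * [TOC])

where ``q`` is mg(TOC) adsorbed per g of catalyst, ``q0`` the monolayer
capacity and ``K_ads`` (L/mg == 1/ppm) the equilibrium constant.  Parameters
are estimated, as is conventional, from the linearised form

    [TOC]/q = 1/(q0*K_ads) + [TOC]/q0

by ordinary least squares; a nonlinear refit is available as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AdsorptionParameters",
    "AdsorptionDataset",
    "LangmuirFit",
    "langmuir_q",
    "q_from_mass_balance",
    "fit_langmuir_linear",
    "fit_langmuir_nonlinear",
]


@dataclass(frozen=True)
class AdsorptionParameters:
    q0: float  #: monolayer capacity, mg(TOC)/g catalyst
    k_ads: float  #: equilibrium constant, 1/ppm

    def __post_init__(self) -> None:
        if self.q0 <= 0 or self.k_ads <= 0:
            raise ValueError("q0 and k_ads must be positive")


#: parameters fitted from the dark-adsorption experiments (30 C, pH 6.9,
#: 0.6 g/L catalyst) — used as generator defaults, not as fit targets
DARK_ADSORPTION = AdsorptionParameters(q0=1.52, k_ads=4.42e-3)


@dataclass
class AdsorptionDataset:
    """Equilibrium dark-adsorption records.

    ``data`` columns: ``toc_eq_ppm`` (equilibrium TOC in solution) and
    ``q_mg_g`` (adsorbed amount); optional ``toc0_ppm``, ``catalyst_g_L``,
    ``volume_L``.
    """

    data: pd.DataFrame
    catalyst_g_l: float = 0.6
    temperature_c: float = 30.0
    ph: float = 6.9

    def __post_init__(self) -> None:
        missing = {"toc_eq_ppm", "q_mg_g"} - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing required columns: {sorted(missing)}")
        if (self.data["toc_eq_ppm"] < 0).any():
            raise ValueError("toc_eq_ppm must be non-negative")

    def __len__(self) -> int:
        return len(self.data)


def langmuir_q(toc, params: AdsorptionParameters):
    """Adsorbed amount (mg/g) at solution concentration ``toc`` (ppm)."""
    toc = np.asarray(toc, dtype=float)
    if np.any(toc < 0):
        raise ValueError("toc must be non-negative")
    out = params.q0 * params.k_ads * toc / (1.0 + params.k_ads * toc)
    return out if out.ndim else float(out)


def q_from_mass_balance(toc0, toc_eq, volume_l, mass_g):
    """Adsorbed amount from the solution mass balance ``(TOC0-TOCeq)*V/m``, mg/g."""
    toc0 = np.asarray(toc0, dtype=float)
    return (toc0 - np.asarray(toc_eq, float)) * volume_l / mass_g


@dataclass
class LangmuirFit:
    """Linearised Langmuir fit result with diagnostics."""

    params: AdsorptionParameters | None
    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray
    success: bool
    message: str = ""
    nonlinear: AdsorptionParameters | None = field(default=None)


def fit_langmuir_linear(dataset: AdsorptionDataset) -> LangmuirFit:
    """Estimate ``(q0, K_ads)`` by OLS on the linearised isotherm.

    Regresses ``[TOC]/q`` on ``[TOC]``: slope ``1/q0``, intercept
    ``1/(q0*K_ads)``.  A non-positive slope or intercept means the data are
    inconsistent with monolayer adsorption and is returned as a flagged
    failure rather than an exception.
    """
    df = dataset.data
    mask = (df["toc_eq_ppm"] > 0) & (df["q_mg_g"] > 0)
    x = df.loc[mask, "toc_eq_ppm"].to_numpy(float)
    y = x / df.loc[mask, "q_mg_g"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 positive equilibrium records to fit")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    if res.slope <= 0 or res.intercept <= 0:
        return LangmuirFit(
            params=None,
            slope=res.slope,
            intercept=res.intercept,
            r_squared=res.rvalue**2,
            residuals=resid,
            success=False,
            message="non-positive slope or intercept: data inconsistent with "
            "the monolayer Langmuir model",
        )
    q0 = 1.0 / res.slope
    k_ads = res.slope / res.intercept
    fit = LangmuirFit(
        params=AdsorptionParameters(q0=q0, k_ads=k_ads),
        slope=res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        residuals=resid,
        success=True,
    )
    return fit


def fit_langmuir_nonlinear(
    dataset: AdsorptionDataset, start: AdsorptionParameters | None = None
) -> AdsorptionParameters:
    """Nonlinear least-squares refit of the isotherm (diagnostic only).

    Agrees with the linearised fit on noise-free data; under noise the two
    weight the observations differently and may diverge.
    """
    df = dataset.data
    x = df["toc_eq_ppm"].to_numpy(float)
    y = df["q_mg_g"].to_numpy(float)
    p0 = (start.q0, start.k_ads) if start else (max(y.max(), 1e-6), 1.0 / max(x.mean(), 1.0))
    popt, _ = optimize.curve_fit(
        lambda t, q0, k: q0 * k * t / (1.0 + k * t), x, y, p0=p0, maxfev=20000
    )
    return AdsorptionParameters(q0=float(popt[0]), k_ads=float(popt[1]))
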