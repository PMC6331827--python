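"""CSV input/output for time series and adsorption tables.

Schemas
-------
TOC time series: required columns ``t30w_min`` and ``toc_ppm``; optional
``estrogens_ppm``; any further columns are preserved on the round trip
(stored under ``metadata['extra']``).

Adsorption data: required ``toc0_ppm``, ``toc_eq_ppm``, ``catalyst_g_L``,
``volume_L``; the adsorbed amount is taken from an optional ``q_mg_g``
column or computed from the mass balance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adsorption import AdsorptionDataset, q_from_mass_balance
from .kinetics import TOCTimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_adsorption_csv",
    "write_adsorption_csv",
]

_TS_REQUIRED = ("t30w_min", "toc_ppm")
_ADS_REQUIRED = ("toc0_ppm", "toc_eq_ppm", "catalyst_g_L", "volume_L")


def _check_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: column {col!r} has a non-numeric value in data row "
                f"{row + 1} ({df[col].iloc[row]!r})"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ValueError(f"{path}: column {col!r} is missing a value in data row {row + 1}")
        df[col] = coerced
    return df


def read_timeseries(path) -> TOCTimeSeries:
    """Read a TOC trajectory CSV; informative errors name column and row."""
    df = pd.read_csv(path)
    missing = set(_TS_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    numeric = list(_TS_REQUIRED) + (["estrogens_ppm"] if "estrogens_ppm" in df else [])
    df = _check_numeric(df, numeric, path)
    extra = {
        c: df[c].to_numpy()
        for c in df.columns
        if c not in (*_TS_REQUIRED, "estrogens_ppm")
    }
    return TOCTimeSeries(
        t30w_min=df["t30w_min"].to_numpy(),
        toc_ppm=df["toc_ppm"].to_numpy(),
        estrogens_ppm=df["estrogens_ppm"].to_numpy() if "estrogens_ppm" in df else None,
        metadata={"extra": extra} if extra else {},
    )


def write_timeseries(series: TOCTimeSeries, path) -> None:
    data = {"t30w_min": series.t30w_min, "toc_ppm": series.toc_ppm}
    if series.estrogens_ppm is not None:
        data["estrogens_ppm"] = series.estrogens_ppm
    for name, col in series.metadata.get("extra", {}).items():
        data[name] = col
    pd.DataFrame(data).to_csv(path, index=False)


def read_adsorption_csv(path) -> AdsorptionDataset:
    df = pd.read_csv(path)
    missing = set(_ADS_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    numeric = list(_ADS_REQUIRED) + (["q_mg_g"] if "q_mg_g" in df else [])
    df = _check_numeric(df, numeric, path)
    if "q_mg_g" not in df:
        df["q_mg_g"] = q_from_mass_balance(
            df["toc0_ppm"], df["toc_eq_ppm"], df["volume_L"],
            df["catalyst_g_L"] * df["volume_L"],
        )
    return AdsorptionDataset(data=df, catalyst_g_l=float(df["catalyst_g_L"].iloc[0]))


def write_adsorption_csv(dataset: AdsorptionDataset, path) -> None:
    dataset.data.to_csv(path, index=False)
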