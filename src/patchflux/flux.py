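"""Chamber concentration series -> daily areal N2O-N flux.

The flux calculation is the standard static-chamber one: the headspace
N2O mole fraction is regressed on elapsed minutes (OLS over all points, no
point dropping), and the slope is converted to an areal mass flux with the
ideal gas law,

    F [mg N2O-N m^-2 d^-1] = b [ppb min^-1] * 1440 * 1e-9
                             * P / (R * T) [mol air m^-3]
                             * (V/A) [m] * M_N [g mol^-1] * 1e3

where P is barometric pressure (Pa), T chamber air temperature (K),
R = 8.314 J mol^-1 K^-1, V/A the headspace ratio (chamber height for a
cylinder), and M_N = 28 g N per mol N2O (two N atoms).  Fluxes are
reported in nitrogen units and negative fluxes (soil uptake or fit noise)
are retained.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    CampaignDataset,
    ChamberGeometry,
    ConcentrationSeries,
    FluxEstimate,
    QualityFlag,
    SlopeFit,
)

R_GAS = 8.314  # J mol^-1 K^-1
MOLAR_MASS_N2O_N = 28.0  # g N per mol N2O
MINUTES_PER_DAY = 1440.0

DEFAULT_R2_THRESHOLD = 0.7


def fit_chamber_slope(series: ConcentrationSeries) -> SlopeFit:
    """OLS line of concentration (ppb) on elapsed minutes.

    Uses every point.  With fewer than 3 points or zero concentration
    variance the fit is still returned (slope possibly 0, r^2 NaN) and the
    situation is carried as a quality flag by :func:`flag_quality`, not as
    an exception — one bad chamber must not abort a campaign.
    """
    t = np.asarray(series.minutes, dtype=float)
    y = np.asarray(series.concentrations, dtype=float)
    n = t.size
    if n < 2:
        return SlopeFit(slope=0.0, intercept=float(y[0]) if n else math.nan,
                        r_squared=math.nan, n_points=n)
    tbar, ybar = t.mean(), y.mean()
    sxx = float(((t - tbar) ** 2).sum())
    sxy = float(((t - tbar) * (y - ybar)).sum())
    syy = float(((y - ybar) ** 2).sum())
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    if syy == 0.0:
        r2 = math.nan  # constant series: r^2 undefined
    else:
        r2 = (sxy * sxy) / (sxx * syy)
    return SlopeFit(slope=slope, intercept=intercept, r_squared=r2, n_points=n)


def flux_per_unit_slope(geom: ChamberGeometry, temp_c: float, pressure_kpa: float) -> float:
    """Flux (mg N2O-N m^-2 d^-1) produced by a slope of 1 ppb min^-1."""
    if not (temp_c > -40):
        raise ValueError(f"non-physical chamber temperature {temp_c} degC")
    if not (50 < pressure_kpa < 110):
        raise ValueError(f"non-physical pressure {pressure_kpa} kPa")
    t_k = temp_c + 273.15
    molar_density = (pressure_kpa * 1000.0) / (R_GAS * t_k)  # mol m^-3
    return MINUTES_PER_DAY * 1e-9 * molar_density * geom.headspace_ratio * MOLAR_MASS_N2O_N * 1e3


def ideal_gas_flux(
    fit: SlopeFit,
    geom: ChamberGeometry,
    temp_c: float,
    pressure_kpa: float,
    chamber_id: str = "",
    date=None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> FluxEstimate:
    """Convert a concentration slope to a daily areal flux estimate.

    Exactly linear in the slope and in the headspace ratio; strictly
    decreasing in temperature at fixed slope and pressure.
    """
    k = flux_per_unit_slope(geom, temp_c, pressure_kpa)
    return FluxEstimate(
        chamber_id=chamber_id,
        date=date,
        flux=fit.slope * k,
        slope_fit=fit,
        quality_flag=flag_quality(fit, r2_threshold),
    )


def slope_for_flux(
    flux: float, geom: ChamberGeometry, temp_c: float, pressure_kpa: float
) -> float:
    """Inverse of the ideal-gas conversion: slope (ppb min^-1) for a target flux."""
    return flux / flux_per_unit_slope(geom, temp_c, pressure_kpa)


def flag_quality(fit: SlopeFit, r2_threshold: float = DEFAULT_R2_THRESHOLD) -> QualityFlag:
    """Quality flag for a slope fit.  Flags annotate; they never drop data."""
    if fit.n_points < 3:
        return QualityFlag.TOO_FEW_POINTS
    if math.isnan(fit.r_squared):
        return QualityFlag.CONSTANT
    if fit.r_squared < r2_threshold:
        return QualityFlag.LOW_R2
    return QualityFlag.OK


def estimate_all_fluxes(
    ds: CampaignDataset,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> pd.DataFrame:
    """One flux estimate per concentration series in the dataset.

    Returns a tidy table with columns chamber_id, date, flux_mg_n_m2_d,
    slope_ppb_min, intercept_ppb, r2, n_points, flag.  Negative fluxes are
    retained; per-series problems surface as flags.
    """
    rows = []
    for s in ds.series:
        fit = fit_chamber_slope(s)
        est = ideal_gas_flux(
            fit, ds.geometry, s.chamber_temperature, s.pressure,
            chamber_id=s.chamber_id, date=s.deployment_date,
            r2_threshold=r2_threshold,
        )
        rows.append(
            {
                "chamber_id": s.chamber_id,
                "date": s.deployment_date,
                "flux_mg_n_m2_d": est.flux,
                "slope_ppb_min": fit.slope,
                "intercept_ppb": fit.intercept,
                "r2": fit.r_squared,
                "n_points": fit.n_points,
                "flag": est.quality_flag.value,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["chamber_id", "date"], kind="stable").reset_index(drop=True)
    return df
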