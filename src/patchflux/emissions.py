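"""Cumulative N2O emissions and urine-N emission factors.

Daily fluxes are integrated over the monitoring window by trapezoidal
interpolation between sampling days.  The urine-N emission factor is

    EF (%) = (N2O-N emitted - N2O-N control) / N applied * 100

with "emitted" and "control" the cumulative emissions (kg N2O-N ha^-1) of
urine and control patches over the same window.  Control subtraction uses
the mean cumulative emission of the control replicates within the same
site x pasture condition; EF is computed per urine replicate and site EF
is the mean of replicate EFs.  When the applied-N amount is unknown the
EF is undefined (NaN), never zero.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    CampaignDataset,
    ChamberGeometry,
    CumulativeEmission,
    EmissionFactor,
    EmissionSeries,
    PastureCondition,
    Treatment,
    UrineApplication,
)

#: mg m^-2 -> kg ha^-1
MG_M2_TO_KG_HA = 0.01


class IntegrationError(ValueError):
    """Emission series cannot be integrated (too few points, bad axis)."""


class UndefinedNApplied(ValueError):
    """Applied urine-N cannot be determined; EF undefined."""


def trapezoid_cumulative(series: EmissionSeries) -> CumulativeEmission:
    """Time-integrate daily fluxes between sampling days (trapezoid rule).

    Sum over adjacent day pairs of 0.5*(f_i + f_{i+1})*(d_{i+1} - d_i),
    converted from mg m^-2 to kg ha^-1.  Exact for fluxes linear in time
    and invariant to inserting interpolated points.  No extrapolation
    beyond the first/last sampled day.
    """
    days = np.asarray(series.days, dtype=float)
    fluxes = np.asarray(series.fluxes, dtype=float)
    if days.size < 2:
        raise IntegrationError(
            f"unit {series.unit.chamber_id}: need >= 2 sampling days, got {days.size}"
        )
    if np.any(np.diff(days) <= 0):
        raise IntegrationError(
            f"unit {series.unit.chamber_id}: days not strictly increasing: {days.tolist()}"
        )
    total_mg_m2 = float(np.trapezoid(fluxes, days))
    return CumulativeEmission(
        unit=series.unit,
        value=total_mg_m2 * MG_M2_TO_KG_HA,
        window=(float(days[0]), float(days[-1])),
    )


def derive_n_applied(app: UrineApplication, geom: ChamberGeometry) -> float:
    """Applied urine-N rate (kg N ha^-1) from volume x concentration / area.

    (volume [L] * concentration [g N L^-1]) / applied_area [m^2] gives
    g N m^-2; x10 converts to kg N ha^-1.  ``applied_area`` defaults to the
    chamber base area; it is an explicit parameter because the wetted area
    of a urination event need not equal the chamber footprint.
    """
    if app.urine_n_concentration is None:
        raise UndefinedNApplied(
            f"site {app.site_id}: urine N concentration unknown; applied N undefined"
        )
    if app.volume is None:
        raise UndefinedNApplied(f"site {app.site_id}: urine volume unknown")
    area = app.applied_area if app.applied_area is not None else geom.area
    if not (area > 0):
        raise ValueError(f"site {app.site_id}: applied area must be > 0, got {area}")
    grams_n = app.volume * app.urine_n_concentration
    return grams_n / area * 10.0


def resolve_n_applied(app: Optional[UrineApplication], geom: ChamberGeometry) -> Optional[float]:
    """Directly stated applied-N if present, else derived; None when undefined."""
    if app is None:
        return None
    if app.n_applied is not None:
        return app.n_applied
    try:
        return derive_n_applied(app, geom)
    except UndefinedNApplied:
        return None


def emission_factor(
    emitted: float,
    control: float,
    n_applied: Optional[float],
    site_id: str = "",
    pasture_condition: PastureCondition = PastureCondition.LVC,
) -> EmissionFactor:
    """Control-corrected urine-N emission factor, % of applied N.

    Negative values are allowed (control exceeding treatment).  Raises
    :class:`UndefinedNApplied` when ``n_applied`` is missing or
    non-positive: an unknown denominator makes the EF undefined, not zero.
    """
    if n_applied is None or not (n_applied > 0):
        raise UndefinedNApplied(
            f"site {site_id or '?'}: n_applied={n_applied!r}; emission factor undefined"
        )
    value = (emitted - control) / n_applied * 100.0
    return EmissionFactor(
        site_id=site_id,
        pasture_condition=pasture_condition,
        value=value,
        emitted=emitted,
        control=control,
        n_applied=n_applied,
    )


def unit_means(values: Iterable[float]) -> tuple[float, float, int]:
    """(mean, SEM, n) of a group; SEM is NaN for singletons.

    SEM uses the sample standard deviation (n-1 denominator) over sqrt(n).
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("empty group")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return mean, sem, n


# ---------------------------------------------------------------------------
# Campaign-level table builders


def build_emission_series(flux_table: pd.DataFrame, ds: CampaignDataset) -> list[EmissionSeries]:
    """Assemble per-unit emission series on the elapsed-day axis.

    Day 0 is the site's urine application day; the pre-application
    baseline sample has a negative day.  Sites without an application
    record anchor day 0 at their first sampling date.
    """
    chamber_map = ds.chamber_map
    origin: dict[str, object] = {a.site_id: a.application_date for a in ds.urine}
    out: list[EmissionSeries] = []
    for chamber_id, grp in flux_table.groupby("chamber_id", sort=True):
        unit = chamber_map[str(chamber_id)]
        anchor = origin.get(unit.site_id)
        grp = grp.sort_values("date")
        if anchor is None:
            anchor = grp["date"].iloc[0]
        days = tuple(float((d - anchor).days) for d in grp["date"])
        out.append(EmissionSeries(unit=unit, days=days, fluxes=tuple(grp["flux_mg_n_m2_d"])))
    return out


def cumulative_table(
    flux_table: pd.DataFrame,
    ds: CampaignDataset,
    monitoring_bounds: tuple[float, float] = (18.0, 24.0),
) -> pd.DataFrame:
    """Per-unit cumulative emissions (kg N2O-N ha^-1) with window check.

    ``window_ok`` records whether the sampled window length falls inside
    ``monitoring_bounds`` (checked, not enforced).
    """
    rows = []
    for es in build_emission_series(flux_table, ds):
        cum = trapezoid_cumulative(es)
        length = cum.window[1] - cum.window[0]
        rows.append(
            {
                "site": es.unit.site_id,
                "condition": es.unit.pasture_condition.value,
                "treatment": es.unit.treatment.value,
                "replicate": es.unit.replicate,
                "chamber_id": es.unit.chamber_id,
                "kg_n2o_n_per_ha": cum.value,
                "window_days": length,
                "window_ok": monitoring_bounds[0] <= length <= monitoring_bounds[1],
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["site", "condition", "treatment", "replicate"], kind="stable"
    ).reset_index(drop=True)


def ef_table(cum_table: pd.DataFrame, ds: CampaignDataset) -> pd.DataFrame:
    """Per-replicate emission factors with site x condition control means.

    Each urine replicate's cumulative emission is corrected by the mean of
    the control replicates in the same site x condition, then divided by
    the site's applied N.  Sites with unknown applied N get NaN EFs.
    """
    rows = []
    for (site, cond), grp in cum_table.groupby(["site", "condition"], sort=True):
        controls = grp.loc[grp["treatment"] == Treatment.CONTROL.value, "kg_n2o_n_per_ha"]
        control_mean = float(controls.mean()) if len(controls) else 0.0
        n_app = resolve_n_applied(ds.urine_for_site(str(site)), ds.geometry)
        for _, r in grp[grp["treatment"] == Treatment.URINE.value].iterrows():
            if n_app is None:
                ef_val = math.nan
            else:
                ef_val = emission_factor(
                    float(r["kg_n2o_n_per_ha"]), control_mean, n_app,
                    site_id=str(site), pasture_condition=PastureCondition(str(cond)),
                ).value
            rows.append(
                {
                    "site": site,
                    "condition": cond,
                    "replicate": int(r["replicate"]),
                    "ef_percent": ef_val,
                    "emitted": float(r["kg_n2o_n_per_ha"]),
                    "control_mean": control_mean,
                    "n_applied": n_app if n_app is not None else math.nan,
                }
            )
    return pd.DataFrame(rows).reset_index(drop=True)


def site_ef_means(ef: pd.DataFrame) -> pd.DataFrame:
    """Site x condition EF means with SEM over replicates."""
    rows = []
    for (site, cond), grp in ef.groupby(["site", "condition"], sort=True):
        vals = grp["ef_percent"].dropna()
        if len(vals) == 0:
            rows.append({"site": site, "condition": cond, "ef_percent": math.nan,
                         "sem": math.nan, "n": 0})
            continue
        mean, sem, n = unit_means(vals)
        rows.append({"site": site, "condition": cond, "ef_percent": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)
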