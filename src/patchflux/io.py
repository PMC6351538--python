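"""Campaign CSV ingestion, validation, and deterministic result writing.

Input layout (long/tidy, one directory):

- ``design.csv``  — site_id,country,condition,treatment,replicate,chamber_id
- ``gas.csv``     — chamber_id,date,minute,n2o_ppb,temp_c,pressure_kpa
- ``urine.csv``   — site_id,volume_l,urine_n_g_per_l,n_applied_kg_ha,application_date
- ``weather.csv`` — site_id,date,rain_mm,tmean_c
- ``sites.csv``   — site_id,country,location_name,texture,ph,bulk_density,soc_pct,son_pct (optional)

Units are fixed at ingestion: ppb for concentration (``concentration_unit:
ppm`` in the config converts), deg C, kPa.  Missing per-deployment
temperature/pressure fall back to config defaults with a logged warning.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .types import (
    CampaignDataset,
    ChamberGeometry,
    ConcentrationSeries,
    ExperimentalUnit,
    PastureCondition,
    SiteMetadata,
    Treatment,
    UrineApplication,
    WeatherSeries,
)

logger = logging.getLogger(__name__)

DEFAULT_PRESSURE_KPA = 101.325
DEFAULT_TEMPERATURE_C = 25.0


class CampaignError(ValueError):
    """Base class for campaign ingestion errors."""


class SchemaError(CampaignError):
    """A required column or file is missing."""


class LinkageError(CampaignError):
    """A record references a chamber/site that does not exist."""


class IntegrityError(CampaignError):
    """A design-uniqueness constraint is violated."""


_REQUIRED = {
    "design.csv": ["site_id", "condition", "treatment", "replicate", "chamber_id"],
    "gas.csv": ["chamber_id", "date", "minute", "n2o_ppb"],
    "urine.csv": ["site_id", "application_date"],
    "weather.csv": ["site_id", "date", "rain_mm", "tmean_c"],
}


def _check_columns(df: pd.DataFrame, fname: str) -> None:
    missing = [c for c in _REQUIRED.get(fname, []) if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing required column(s) {missing}")


def _opt(row: pd.Series, col: str) -> Optional[float]:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def _parse_date(v) -> _dt.date:
    if isinstance(v, _dt.date) and not isinstance(v, _dt.datetime):
        return v
    return pd.Timestamp(v).date()


def read_campaign(
    data_dir: Union[str, Path],
    config: Optional[Mapping] = None,
) -> CampaignDataset:
    """Read the five campaign CSVs under ``data_dir`` into a linked dataset.

    ``config`` keys (all optional):

    - ``geometry``: {``height_m``, ``diameter_m``} (default 0.10 m x 0.25 m)
    - ``defaults``: {``pressure_kpa``, ``temperature_c``} used when gas.csv
      lacks the column or has missing values
    - ``concentration_unit``: ``ppb`` (default) or ``ppm``

    Raises :class:`SchemaError` for missing columns, :class:`LinkageError`
    for orphan chamber ids, :class:`IntegrityError` for duplicate
    (site, condition, treatment, replicate) rows.
    """
    cfg = dict(config or {})
    data_dir = Path(data_dir)
    geom_cfg = cfg.get("geometry", {})
    geometry = ChamberGeometry(
        height=float(geom_cfg.get("height_m", 0.10)),
        internal_diameter=float(geom_cfg.get("diameter_m", 0.25)),
    )
    defaults = cfg.get("defaults", {})
    p_default = float(defaults.get("pressure_kpa", DEFAULT_PRESSURE_KPA))
    t_default = float(defaults.get("temperature_c", DEFAULT_TEMPERATURE_C))
    conc_scale = 1000.0 if cfg.get("concentration_unit", "ppb") == "ppm" else 1.0

    def load(name: str, required: bool = True) -> Optional[pd.DataFrame]:
        path = data_dir / name
        if not path.exists():
            if required:
                raise SchemaError(f"{name}: file not found under {data_dir}")
            return None
        df = pd.read_csv(path)
        _check_columns(df, name)
        return df

    design = load("design.csv")
    gas = load("gas.csv")
    urine_df = load("urine.csv", required=False)
    weather_df = load("weather.csv", required=False)
    sites_df = load("sites.csv", required=False)

    # --- design -----------------------------------------------------------
    units: list[ExperimentalUnit] = []
    seen_keys: set[tuple] = set()
    for _, row in design.iterrows():
        u = ExperimentalUnit(
            site_id=str(row["site_id"]),
            pasture_condition=PastureCondition(str(row["condition"])),
            treatment=Treatment(str(row["treatment"])),
            replicate=int(row["replicate"]),
            chamber_id=str(row["chamber_id"]),
        )
        if u.key in seen_keys:
            raise IntegrityError(f"design.csv: duplicate unit {u.key}")
        seen_keys.add(u.key)
        units.append(u)
    chamber_ids = {u.chamber_id for u in units}
    if len(chamber_ids) != len(units):
        raise IntegrityError("design.csv: duplicate chamber_id")

    # --- gas --------------------------------------------------------------
    for col, dflt, label in (("temp_c", t_default, "temperature"), ("pressure_kpa", p_default, "pressure")):
        if col not in gas.columns:
            logger.warning("gas.csv lacks %s column; filling %s = %s", col, label, dflt)
            gas[col] = dflt
        elif gas[col].isna().any():
            n = int(gas[col].isna().sum())
            logger.warning("gas.csv: %d missing %s values filled with %s", n, label, dflt)
            gas[col] = gas[col].fillna(dflt)

    orphans = sorted(set(gas["chamber_id"].astype(str)) - chamber_ids)
    if orphans:
        raise LinkageError(f"gas.csv: chamber_id(s) {orphans} not present in design.csv")

    series: list[ConcentrationSeries] = []
    for (chamber_id, date), grp in gas.groupby(["chamber_id", "date"], sort=True):
        grp = grp.sort_values("minute")
        series.append(
            ConcentrationSeries(
                chamber_id=str(chamber_id),
                deployment_date=_parse_date(date),
                minutes=[float(m) for m in grp["minute"]],
                concentrations=[float(c) * conc_scale for c in grp["n2o_ppb"]],
                chamber_temperature=float(grp["temp_c"].iloc[0]),
                pressure=float(grp["pressure_kpa"].iloc[0]),
            )
        )

    # --- urine ------------------------------------------------------------
    urine: list[UrineApplication] = []
    if urine_df is not None:
        for _, row in urine_df.iterrows():
            urine.append(
                UrineApplication(
                    site_id=str(row["site_id"]),
                    application_date=_parse_date(row["application_date"]),
                    volume=_opt(row, "volume_l"),
                    urine_n_concentration=_opt(row, "urine_n_g_per_l"),
                    applied_area=_opt(row, "applied_area_m2"),
                    n_applied=_opt(row, "n_applied_kg_ha"),
                )
            )

    # --- weather ----------------------------------------------------------
    weather: list[WeatherSeries] = []
    if weather_df is not None:
        for site_id, grp in weather_df.groupby("site_id", sort=True):
            grp = grp.sort_values("date")
            weather.append(
                WeatherSeries(
                    site_id=str(site_id),
                    dates=[_parse_date(d) for d in grp["date"]],
                    rainfall=[float(r) for r in grp["rain_mm"]],
                    mean_air_temperature=[float(t) for t in grp["tmean_c"]],
                )
            )

    # --- sites ------------------------------------------------------------
    sites: list[SiteMetadata] = []
    if sites_df is not None:
        for _, row in sites_df.iterrows():
            sites.append(
                SiteMetadata(
                    site_id=str(row["site_id"]),
                    country=str(row["country"]) if "country" in row and pd.notna(row["country"]) else None,
                    location_name=str(row["location_name"]) if "location_name" in row and pd.notna(row["location_name"]) else None,
                    texture_class=str(row["texture"]) if "texture" in row and pd.notna(row["texture"]) else None,
                    pH=_opt(row, "ph"),
                    bulk_density=_opt(row, "bulk_density"),
                    SOC=_opt(row, "soc_pct"),
                    SON=_opt(row, "son_pct"),
                )
            )

    ds = CampaignDataset(
        units=units, series=series, urine=urine, weather=weather,
        sites=sites, geometry=geometry,
    )
    logger.info(
        "read campaign: %d units, %d series, %d urine records, %d weather sites",
        len(units), len(series), len(urine), len(weather),
    )
    return ds


def validate_campaign(ds: CampaignDataset) -> list[str]:
    """Enumerate every invariant violation; empty list means clean.

    Never raises on dirty data — every problem is reported with record
    coordinates so a campaign can be fixed in one pass.  Informational
    entries (prefix ``info:``) flag sites whose emission factor will be
    undefined for lack of an applied-N value.
    """
    report: list[str] = []

    # design uniqueness + completeness
    keys: set[tuple] = set()
    for u in ds.units:
        if u.key in keys:
            report.append(f"design: duplicate unit {u.key}")
        keys.add(u.key)
    by_site: dict[str, list[ExperimentalUnit]] = {}
    for u in ds.units:
        by_site.setdefault(u.site_id, []).append(u)
    for site_id, site_units in by_site.items():
        conds = {u.pasture_condition for u in site_units}
        if conds != {PastureCondition.LVC, PastureCondition.AVC}:
            report.append(f"design site={site_id}: missing pasture condition {sorted({c.value for c in ({PastureCondition.LVC, PastureCondition.AVC} - conds)})}")
        for cond in conds:
            treats = {u.treatment for u in site_units if u.pasture_condition == cond}
            if treats != {Treatment.URINE, Treatment.CONTROL}:
                report.append(f"design site={site_id} condition={cond.value}: missing treatment")

    chambers = {u.chamber_id for u in ds.units}
    for s in ds.series:
        if s.chamber_id not in chambers:
            report.append(f"series chamber={s.chamber_id} date={s.deployment_date}: chamber not in design")
        report.extend(s.violations())

    urine_sites = set()
    for a in ds.urine:
        report.extend(a.violations())
        urine_sites.add(a.site_id)
        if a.n_applied is None and a.urine_n_concentration is None:
            report.append(
                f"info: urine site={a.site_id}: applied N unknown "
                "(no concentration, no direct value) — EF undefined for site"
            )
        elif (
            a.n_applied is not None
            and a.urine_n_concentration is not None
            and a.volume is not None
        ):
            from .emissions import derive_n_applied

            derived = derive_n_applied(a, ds.geometry)
            if derived > 0 and abs(derived - a.n_applied) / derived > 0.01:
                report.append(
                    f"urine site={a.site_id}: stated n_applied {a.n_applied} "
                    f"inconsistent with derived {derived:.4g} kg N ha^-1 (>1%)"
                )
    for site_id in by_site:
        has_urine_units = any(u.treatment == Treatment.URINE for u in by_site[site_id])
        if has_urine_units and site_id not in urine_sites:
            report.append(f"design site={site_id}: urine treatment present but no urine application record")

    for w in ds.weather:
        report.extend(w.violations())
    for m in ds.sites:
        report.extend(m.violations())

    return report


# ---------------------------------------------------------------------------
# Result writing

#: canonical column order per table name; unlisted tables keep their order
_TABLE_COLUMNS = {
    "fluxes": ["chamber_id", "date", "flux_mg_n_m2_d", "slope_ppb_min", "r2", "flag"],
    "cumulative": ["site", "condition", "treatment", "replicate", "kg_n2o_n_per_ha", "window_days"],
    "ef": ["site", "condition", "replicate", "ef_percent", "emitted", "control_mean", "n_applied"],
}


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: Union[str, Path]) -> list[Path]:
    """Write result tables as ``<name>.csv`` with deterministic formatting.

    Columns follow the canonical order where one is defined; floats are
    rendered at 6 significant digits so reruns are byte-diffable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        cols = _TABLE_COLUMNS.get(name)
        if cols is not None:
            ordered = [c for c in cols if c in df.columns]
            ordered += [c for c in df.columns if c not in ordered]
            df = df[ordered]
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
        written.append(path)
        logger.info("wrote %s (%d rows)", path, len(df))
    return written


def campaign_to_frames(ds: CampaignDataset) -> dict[str, pd.DataFrame]:
    """Flatten a dataset back to the five tidy CSV tables (inverse of read)."""
    design = pd.DataFrame(
        [
            {
                "site_id": u.site_id,
                "condition": u.pasture_condition.value,
                "treatment": u.treatment.value,
                "replicate": u.replicate,
                "chamber_id": u.chamber_id,
            }
            for u in ds.units
        ]
    )
    gas = pd.DataFrame(
        [
            {
                "chamber_id": s.chamber_id,
                "date": s.deployment_date.isoformat(),
                "minute": m,
                "n2o_ppb": c,
                "temp_c": s.chamber_temperature,
                "pressure_kpa": s.pressure,
            }
            for s in ds.series
            for m, c in zip(s.minutes, s.concentrations)
        ]
    )
    urine = pd.DataFrame(
        [
            {
                "site_id": a.site_id,
                "volume_l": a.volume if a.volume is not None else math.nan,
                "urine_n_g_per_l": a.urine_n_concentration if a.urine_n_concentration is not None else math.nan,
                "n_applied_kg_ha": a.n_applied if a.n_applied is not None else math.nan,
                "application_date": a.application_date.isoformat(),
            }
            for a in ds.urine
        ]
    )
    weather = pd.DataFrame(
        [
            {"site_id": w.site_id, "date": d.isoformat(), "rain_mm": r, "tmean_c": t}
            for w in ds.weather
            for d, r, t in zip(w.dates, w.rainfall, w.mean_air_temperature)
        ]
    )
    sites = pd.DataFrame(
        [
            {
                "site_id": m.site_id,
                "country": m.country,
                "location_name": m.location_name,
                "texture": m.texture_class,
                "ph": m.pH,
                "bulk_density": m.bulk_density,
                "soc_pct": m.SOC,
                "son_pct": m.SON,
            }
            for m in ds.sites
        ]
    )
    return {"design": design, "gas": gas, "urine": urine, "weather": weather, "sites": sites}


def write_campaign(ds: CampaignDataset, out_dir: Union[str, Path]) -> list[Path]:
    """Write a dataset as the five campaign CSVs readable by read_campaign."""
    return write_results(campaign_to_frames(ds), out_dir)
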