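"""End-to-end orchestration: ingest -> fluxes -> cumulative -> EF -> inference.

Every stage is a thin call into the corresponding module; the pipeline
adds only sequencing, a run manifest (config hash, record counts, quality
flag tally, stage errors), and the report renderer.  A failing inference
stage is recorded in the manifest and the remaining stages still run, so
partial results are always available.

``run_inference_from_site_table`` is the documented side entry point: it
accepts site-level cumulative emissions directly (the shape published
summary tables come in), bypassing the chamber stage, so the inference
layer can be exercised when raw chamber series are not available.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import emissions as em
from . import inference as inf
from .flux import DEFAULT_R2_THRESHOLD, estimate_all_fluxes
from .io import validate_campaign
from .types import CampaignDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis knobs, with defaults materialized and hashable.

    ``ef_anova_mode``: 'site_mean' (one EF per site x condition, the
    default) or 'replicate' (replicate EFs with site as block).
    Transform parameters left None are derived from the data and recorded
    in the result tables.
    """

    r2_threshold: float = DEFAULT_R2_THRESHOLD
    log_offset: Optional[float] = None  # cumulative-emission log transform
    sqrt_shift: Optional[float] = None  # EF square-root transform
    ef_anova_mode: str = "site_mean"
    alpha: float = 0.05
    alpha_regional: float = 0.10
    welch: bool = False
    monitoring_bounds: tuple[float, float] = (18.0, 24.0)
    rainfall_lead_days: int = 7  # rainfall total includes this pre-window
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["monitoring_bounds"] = list(self.monitoring_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "monitoring_bounds" in d:
            d["monitoring_bounds"] = tuple(d["monitoring_bounds"])
        return cls(**d)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    fluxes: pd.DataFrame
    cumulative: pd.DataFrame
    ef: pd.DataFrame
    site_ef: pd.DataFrame
    anova_cumulative: Optional[pd.DataFrame]
    anova_ef: Optional[pd.DataFrame]
    site_tests: pd.DataFrame
    rainfall_regression: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "fluxes": self.fluxes,
            "cumulative": self.cumulative,
            "ef": self.ef,
            "site_ef": self.site_ef,
            "site_tests": self.site_tests,
            "rainfall_regression": self.rainfall_regression,
        }
        if self.anova_cumulative is not None:
            out["anova_cumulative"] = self.anova_cumulative
        if self.anova_ef is not None:
            out["anova_ef"] = self.anova_ef
        return out


def _site_rainfall_totals(ds: CampaignDataset, cfg: AnalysisConfig) -> dict[str, float]:
    """Total rainfall per site over the monitoring window plus the lead week."""
    totals: dict[str, float] = {}
    dates_by_site: dict[str, list] = {}
    cmap = ds.chamber_map
    for s in ds.series:
        u = cmap.get(s.chamber_id)
        if u is not None:
            dates_by_site.setdefault(u.site_id, []).append(s.deployment_date)
    for site_id, dates in dates_by_site.items():
        w = ds.weather_for_site(site_id)
        if w is None or not dates:
            continue
        start = min(dates) - _dt.timedelta(days=cfg.rainfall_lead_days)
        totals[site_id] = w.total_rainfall(start, max(dates))
    return totals


def run_pipeline(ds: CampaignDataset, cfg: Optional[AnalysisConfig] = None) -> PipelineResult:
    """Run the full measurement-to-inference chain on one campaign."""
    cfg = cfg or AnalysisConfig()
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.digest,
        "stage_errors": {},
    }

    violations = validate_campaign(ds)
    manifest["validation"] = violations
    hard = [v for v in violations if not v.startswith("info:")]
    if hard:
        logger.warning("campaign has %d invariant violations", len(hard))

    flux_table = estimate_all_fluxes(ds, r2_threshold=cfg.r2_threshold)
    manifest["n_units"] = len(ds.units)
    manifest["n_series"] = len(ds.series)
    manifest["quality_flags"] = (
        flux_table["flag"].value_counts().to_dict() if not flux_table.empty else {}
    )

    cum = em.cumulative_table(flux_table, ds, monitoring_bounds=cfg.monitoring_bounds)
    ef = em.ef_table(cum, ds)
    site_ef = em.site_ef_means(ef)

    # regional split-plot ANOVA on transformed cumulative emissions
    anova_cum = None
    try:
        vals = cum["kg_n2o_n_per_ha"].to_numpy()
        trans = inf.transformed_values(vals, "log_offset", cfg.log_offset)
        d = cum.rename(columns={"site": "location", "treatment": "nitrogen"}).copy()
        d["y"] = trans
        anova_cum = inf.splitplot_anova(d)
        manifest["log_offset"] = (
            cfg.log_offset if cfg.log_offset is not None else inf.default_log_offset(vals)
        )
    except (inf.DesignError, inf.TransformError) as exc:
        manifest["stage_errors"]["anova_cumulative"] = str(exc)

    # regional blocked one-way ANOVA on transformed EFs
    anova_ef = None
    try:
        if cfg.ef_anova_mode == "site_mean":
            ef_data = site_ef.dropna(subset=["ef_percent"])[["site", "condition", "ef_percent"]]
        elif cfg.ef_anova_mode == "replicate":
            ef_data = ef.dropna(subset=["ef_percent"])[["site", "condition", "ef_percent"]]
        else:
            raise inf.DesignError(f"unknown ef_anova_mode {cfg.ef_anova_mode!r}")
        vals = ef_data["ef_percent"].to_numpy()
        d = ef_data.rename(columns={"site": "location"}).copy()
        d["y"] = inf.transformed_values(vals, "sqrt_shift", cfg.sqrt_shift)
        anova_ef = inf.blocked_oneway_anova(d)
        manifest["sqrt_shift"] = (
            cfg.sqrt_shift if cfg.sqrt_shift is not None else inf.default_sqrt_shift(vals)
        )
    except (inf.DesignError, inf.TransformError) as exc:
        manifest["stage_errors"]["anova_ef"] = str(exc)

    site_tests = inf.site_tests_table(ef, alpha=cfg.alpha, welch=cfg.welch)

    # EF ~ rainfall, per condition, one point per site
    rr_rows = []
    totals = _site_rainfall_totals(ds, cfg)
    for cond, grp in site_ef.dropna(subset=["ef_percent"]).groupby("condition"):
        efs, rains = [], []
        for _, r in grp.iterrows():
            if r["site"] in totals:
                efs.append(float(r["ef_percent"]))
                rains.append(totals[r["site"]])
        try:
            reg = inf.regress_ef_on_rainfall(efs, rains, condition=str(cond))
            rr_rows.append(
                {"condition": reg.condition, "slope_ef_per_mm": reg.slope,
                 "intercept": reg.intercept, "r_squared": reg.r_squared, "n_sites": reg.n}
            )
        except inf.RegressionError as exc:
            manifest["stage_errors"][f"rainfall_regression_{cond}"] = str(exc)
    rainfall_regression = pd.DataFrame(
        rr_rows, columns=["condition", "slope_ef_per_mm", "intercept", "r_squared", "n_sites"]
    )

    return PipelineResult(
        fluxes=flux_table, cumulative=cum, ef=ef, site_ef=site_ef,
        anova_cumulative=anova_cum, anova_ef=anova_ef,
        site_tests=site_tests, rainfall_regression=rainfall_regression,
        manifest=manifest,
    )


def run_inference_from_site_table(
    site_table: pd.DataFrame,
    cfg: Optional[AnalysisConfig] = None,
) -> dict:
    """Inference on site-level cumulative emissions entered directly.

    ``site_table`` needs columns site, condition, cumulative_kg_ha and
    optionally n_applied_kg_ha.  Returns regional means +- SEM per
    condition, the observed range, the blocked one-way ANOVA of the
    log-transformed cumulative values (site as block), and simple
    zero-control EF bounds where applied N is known.  This is the entry
    point for summary tables published without replicate data.
    """
    cfg = cfg or AnalysisConfig()
    out: dict = {}
    regional = {}
    for cond, grp in site_table.groupby("condition"):
        mean, sem, n = em.unit_means(grp["cumulative_kg_ha"])
        regional[str(cond)] = {"mean": mean, "sem": sem, "n": n}
    out["regional_cumulative"] = regional
    vals = site_table["cumulative_kg_ha"]
    out["cumulative_range"] = (float(vals.min()), float(vals.max()))

    try:
        d = site_table.rename(columns={"site": "location"}).copy()
        d["y"] = inf.transformed_values(
            site_table["cumulative_kg_ha"].to_numpy(), "log_offset", cfg.log_offset
        )
        out["anova_cumulative"] = inf.blocked_oneway_anova(d)
    except (inf.DesignError, inf.TransformError) as exc:
        out["anova_cumulative_error"] = str(exc)

    if "n_applied_kg_ha" in site_table.columns:
        ef_rows = []
        for _, r in site_table.iterrows():
            n_app = r["n_applied_kg_ha"]
            if pd.isna(n_app):
                ef_rows.append({"site": r["site"], "condition": r["condition"],
                                "ef_upper_percent": math.nan})
                continue
            e = em.emission_factor(
                float(r["cumulative_kg_ha"]), 0.0, float(n_app), site_id=str(r["site"])
            )
            ef_rows.append({"site": r["site"], "condition": r["condition"],
                            "ef_upper_percent": e.value})
        out["ef_zero_control"] = pd.DataFrame(ef_rows)
    return out


def report_summary(result: PipelineResult) -> str:
    """Fixed-width text report: per-site means +- SEM with letters, regional row.

    Emission-factor cells render '*' where applied N is unknown.
    """
    if result.cumulative.empty:
        return "no data\n"
    lines = []
    header = (
        f"{'site':<10}{'cond':<6}{'cum kg N2O-N/ha':>18}{'EF %':>14}{'letter':>8}"
    )
    lines.append(header)
    lines.append("-" * len(header))
    letters = {
        (r["site"], "LVC"): r["letter_LVC"] for _, r in result.site_tests.iterrows()
    }
    letters.update(
        {(r["site"], "AVC"): r["letter_AVC"] for _, r in result.site_tests.iterrows()}
    )
    urine = result.cumulative[result.cumulative["treatment"] == "urine"]
    for (site, cond), grp in urine.groupby(["site", "condition"], sort=True):
        mean, sem, _ = em.unit_means(grp["kg_n2o_n_per_ha"])
        sem_s = f"({sem:.2f})" if not math.isnan(sem) else "(--)"
        ef_row = result.site_ef[
            (result.site_ef["site"] == site) & (result.site_ef["condition"] == cond)
        ]
        if len(ef_row) and not math.isnan(float(ef_row["ef_percent"].iloc[0])):
            ef_s = f"{float(ef_row['ef_percent'].iloc[0]):.2f}"
        else:
            ef_s = "*"
        lines.append(
            f"{site:<10}{cond:<6}{mean:>10.2f} {sem_s:>7}{ef_s:>14}"
            f"{letters.get((site, cond), ''):>8}"
        )
    lines.append("-" * len(header))
    for cond, grp in urine.groupby("condition", sort=True):
        site_means = grp.groupby("site")["kg_n2o_n_per_ha"].mean()
        mean, sem, n = em.unit_means(site_means)
        sem_s = f"({sem:.2f})" if not math.isnan(sem) else "(--)"
        lines.append(f"{'regional':<10}{cond:<6}{mean:>10.2f} {sem_s:>7}  (n={n} sites)")
    return "\n".join(lines) + "\n"
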