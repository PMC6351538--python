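"""Synthetic multi-site urine-patch campaigns with known ground truth.

The generator is phenomenological: each experimental unit gets a true
daily-flux curve (a flat background for controls, background plus a
surge-decay urine pulse for urine patches), the pipeline's ideal-gas
mapping is inverted to turn the true flux on each sampling day into a
chamber concentration slope, and Gaussian instrument noise is added to
the four headspace concentrations.  Because the measurement model is the
exact inverse of the flux calculation, a zero-noise campaign reproduces
its ground truth identically through the whole pipeline.

The default design mirrors the rainy-season Latin America / Caribbean
campaign the package analyses: 7 sites x 2 pasture conditions (LVC, AVC)
x 2 treatments (urine, control) x 5 replicates, 10 sampling events over
22 days including a pre-application baseline, applied urine-N spanning
roughly 112-1641 kg N ha^-1 across sites, 2 ppb concentration noise, and
an LVC:AVC pulse multiplier of 2.33 so the true regional EF ratio equals
the observed one.  Site-to-site spread is multiplicative log-normal,
shared between the two conditions of a site.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .emissions import MG_M2_TO_KG_HA
from .flux import slope_for_flux
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

AMBIENT_N2O_PPB = 330.0


@dataclass(frozen=True)
class FluxCurveParams:
    """Parameters of one unit's true daily N2O-N flux curve.

    f(t) = baseline + amplitude * [(t / peak) * exp(1 - t / peak)]^(peak / decay)

    for t >= 0 and f(t) = baseline before application; the maximum equals
    baseline + amplitude at t = peak for any decay, and decay = peak
    recovers the plain surge-decay shape.  ``rain_coupling`` optionally
    scales the pulse by (1 + coupling * rain_mm) on each day.
    """

    baseline: float  # mg N2O-N m^-2 d^-1
    pulse_amplitude: float  # mg m^-2 d^-1
    pulse_peak_day: float = 3.0
    pulse_decay: Optional[float] = None  # defaults to pulse_peak_day
    rain_coupling: float = 0.0  # multiplier per mm

    def __post_init__(self) -> None:
        if not (self.pulse_peak_day > 0):
            raise ValueError("pulse_peak_day must be > 0")
        if self.pulse_decay is not None and not (self.pulse_decay > 0):
            raise ValueError("pulse_decay must be > 0")


def simulate_flux_curve(
    params: FluxCurveParams,
    days: Sequence[float],
    rain_mm: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Evaluate the true flux curve on the given elapsed days."""
    t = np.asarray(days, dtype=float)
    peak = params.pulse_peak_day
    decay = params.pulse_decay if params.pulse_decay is not None else peak
    shape = np.zeros_like(t)
    pos = t > 0
    u = t[pos] / peak
    shape[pos] = (u * np.exp(1.0 - u)) ** (peak / decay)
    pulse = params.pulse_amplitude * shape
    if rain_mm is not None and params.rain_coupling != 0.0:
        pulse = pulse * (1.0 + params.rain_coupling * np.asarray(rain_mm, dtype=float))
    return params.baseline + pulse


def simulate_chamber_series(
    true_flux: float,
    geom: ChamberGeometry,
    temp_c: float,
    pressure_kpa: float,
    noise_sd: float,
    rng: np.random.Generator,
    ambient_ppb: float = AMBIENT_N2O_PPB,
    chamber_id: str = "sim",
    deployment_date: _dt.date = _dt.date(2015, 11, 15),
    minutes: Sequence[float] = (0.0, 15.0, 30.0, 45.0),
) -> ConcentrationSeries:
    """One chamber deployment whose noise-free slope encodes ``true_flux``.

    The concentration slope is the exact ideal-gas inverse of the flux,
    so at noise_sd = 0 the pipeline round-trips the truth to float
    precision.  Noise is iid Gaussian on each concentration reading
    (instrument-level), never on the flux.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    slope = slope_for_flux(true_flux, geom, temp_c, pressure_kpa)
    m = np.asarray(minutes, dtype=float)
    conc = ambient_ppb + slope * m
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, size=m.size)
    return ConcentrationSeries(
        chamber_id=chamber_id,
        deployment_date=deployment_date,
        minutes=m.tolist(),
        concentrations=conc.tolist(),
        chamber_temperature=temp_c,
        pressure=pressure_kpa,
    )


@dataclass(frozen=True)
class CampaignDesignSpec:
    """Design and generating parameters of a synthetic campaign.

    Defaults are the reference study conditions (see module docstring).
    ``urine_n_kg_ha`` entries may be None to emulate a site whose urine-N
    could not be assayed (EF undefined there).
    """

    seed: int
    n_sites: int = 7
    n_replicates: int = 5
    sampling_days: tuple[float, ...] = (-1, 0, 1, 2, 3, 7, 10, 14, 17, 21)
    chamber_noise_sd_ppb: float = 2.0
    urine_n_kg_ha: tuple[Optional[float], ...] = (464, 789, 112, 619, 1641, 546, 500)
    condition_multipliers: tuple[tuple[str, float], ...] = (("LVC", 2.33), ("AVC", 1.0))
    baseline_flux: float = 0.5  # mg m^-2 d^-1
    pulse_amplitude_per_kg_n: float = 0.022  # mg m^-2 d^-1 per kg N ha^-1
    pulse_peak_day: float = 3.0
    pulse_decay: Optional[float] = None
    rain_coupling: float = 0.0
    site_effect_sigma: float = 0.8  # log-normal sigma, mean 1
    replicate_effect_sigma: float = 0.3  # log-normal sigma on each unit's curve
    ambient_ppb: float = AMBIENT_N2O_PPB
    pressure_kpa: float = 101.325
    site_mean_temp_c: tuple[float, ...] = (22, 27, 28, 20, 18, 12, 28)
    rain_mean_mm: float = 8.0
    rain_prob: float = 0.45
    start_date: _dt.date = _dt.date(2015, 11, 15)
    geometry: ChamberGeometry = field(
        default_factory=lambda: ChamberGeometry(height=0.10, internal_diameter=0.25)
    )

    def __post_init__(self) -> None:
        if min(self.sampling_days) >= 0:
            raise ValueError("sampling_days must include a pre-application day (< 0)")
        if list(self.sampling_days) != sorted(set(self.sampling_days)):
            raise ValueError("sampling_days must be strictly increasing")


@dataclass
class GroundTruth:
    """Noise-free quantities of a simulated campaign, aligned by unit.

    ``fluxes``      unit x sampling-day true daily fluxes (tidy frame);
    ``cumulative``  per-unit trapezoid integral of the true curve over the
                    sampling days, kg N2O-N ha^-1;
    ``ef``          per site x condition true EF (% of applied N), NaN
                    where applied N is unknown;
    ``condition_multipliers`` the generating LVC/AVC pulse multipliers.
    """

    fluxes: pd.DataFrame
    cumulative: pd.DataFrame
    ef: pd.DataFrame
    condition_multipliers: dict[str, float]

    @property
    def regional_ef_ratio(self) -> float:
        means = self.ef.dropna(subset=["true_ef_percent"]).groupby("condition")["true_ef_percent"].mean()
        return float(means["LVC"] / means["AVC"])


def simulate_campaign(spec: CampaignDesignSpec) -> tuple[CampaignDataset, GroundTruth]:
    """Generate a full campaign and its ground truth.

    Deterministic given the spec (seed included): each site draws from
    its own child RNG stream, so adding a site leaves the other sites'
    data untouched.
    """
    root = np.random.SeedSequence(spec.seed)
    site_seeds = root.spawn(spec.n_sites)
    mult = dict(spec.condition_multipliers)
    days = np.asarray(spec.sampling_days, dtype=float)
    geometry = spec.geometry

    units: list[ExperimentalUnit] = []
    series: list[ConcentrationSeries] = []
    urine: list[UrineApplication] = []
    weather: list[WeatherSeries] = []
    sites_meta: list[SiteMetadata] = []
    truth_flux_rows: list[dict] = []
    truth_cum_rows: list[dict] = []
    truth_ef_rows: list[dict] = []

    for si in range(spec.n_sites):
        rng = np.random.default_rng(site_seeds[si])
        site_id = f"S{si + 1:02d}"
        n_applied = (
            spec.urine_n_kg_ha[si % len(spec.urine_n_kg_ha)]
            if spec.urine_n_kg_ha
            else 500.0
        )
        site_temp = spec.site_mean_temp_c[si % len(spec.site_mean_temp_c)]
        app_date = spec.start_date + _dt.timedelta(days=7 * si)

        # shared multiplicative site effect (mean 1), applied to both
        # conditions so the true LVC:AVC EF ratio equals the multiplier ratio
        sigma = spec.site_effect_sigma
        site_effect = float(rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma))

        # weather: window from one week pre-application to the last sampling day
        first = app_date + _dt.timedelta(days=int(days[0]) - 7)
        last = app_date + _dt.timedelta(days=int(days[-1]))
        wdates = [first + _dt.timedelta(days=k) for k in range((last - first).days + 1)]
        wet = rng.random(len(wdates)) < spec.rain_prob
        amounts = rng.gamma(shape=1.2, scale=spec.rain_mean_mm / 1.2, size=len(wdates))
        rain = np.where(wet, amounts, 0.0)
        tmean = site_temp + rng.normal(0.0, 2.0, size=len(wdates))
        weather.append(
            WeatherSeries(site_id=site_id, dates=wdates, rainfall=rain.tolist(),
                          mean_air_temperature=tmean.tolist())
        )
        rain_by_day = {d: r for d, r in zip(wdates, rain)}

        urine.append(
            UrineApplication(
                site_id=site_id,
                application_date=app_date,
                volume=0.5,
                urine_n_concentration=(
                    None if n_applied is None
                    else n_applied / 10.0 * geometry.area / 0.5
                ),
                n_applied=n_applied,
            )
        )
        sites_meta.append(SiteMetadata(site_id=site_id, country=f"country_{si + 1}"))

        amp_base = 0.0 if n_applied is None else spec.pulse_amplitude_per_kg_n * n_applied
        site_ef_components: dict[str, dict[str, float]] = {}
        for cond in (PastureCondition.LVC, PastureCondition.AVC):
            cum_by_treatment: dict[Treatment, list[float]] = {t: [] for t in Treatment}
            for treat in (Treatment.URINE, Treatment.CONTROL):
                for rep in range(1, spec.n_replicates + 1):
                    chamber_id = f"{site_id}-{cond.value}-{treat.value[:3]}-{rep}"
                    units.append(
                        ExperimentalUnit(
                            site_id=site_id, pasture_condition=cond,
                            treatment=treat, replicate=rep, chamber_id=chamber_id,
                        )
                    )
                    rep_sigma = spec.replicate_effect_sigma
                    rep_effect = (
                        float(rng.lognormal(mean=-rep_sigma**2 / 2.0, sigma=rep_sigma))
                        if rep_sigma > 0 else 1.0
                    )
                    amplitude = (
                        amp_base * mult[cond.value] * site_effect * rep_effect
                        if treat == Treatment.URINE else 0.0
                    )
                    params = FluxCurveParams(
                        baseline=spec.baseline_flux * site_effect,
                        pulse_amplitude=amplitude,
                        pulse_peak_day=spec.pulse_peak_day,
                        pulse_decay=spec.pulse_decay,
                        rain_coupling=spec.rain_coupling,
                    )
                    dep_dates = [app_date + _dt.timedelta(days=int(d)) for d in days]
                    day_rain = [rain_by_day.get(d, 0.0) for d in dep_dates]
                    true_fluxes = simulate_flux_curve(params, days, rain_mm=day_rain)
                    true_cum = float(np.trapezoid(true_fluxes, days)) * MG_M2_TO_KG_HA
                    cum_by_treatment[treat].append(true_cum)
                    truth_cum_rows.append(
                        {
                            "site": site_id, "condition": cond.value,
                            "treatment": treat.value, "replicate": rep,
                            "chamber_id": chamber_id,
                            "true_cumulative_kg_ha": true_cum,
                        }
                    )
                    for d, ddate, f in zip(days, dep_dates, true_fluxes):
                        temp_c = float(tmean[wdates.index(ddate)])
                        truth_flux_rows.append(
                            {
                                "chamber_id": chamber_id, "date": ddate, "day": float(d),
                                "true_flux_mg_n_m2_d": float(f),
                            }
                        )
                        series.append(
                            simulate_chamber_series(
                                float(f), geometry, temp_c, spec.pressure_kpa,
                                spec.chamber_noise_sd_ppb, rng,
                                ambient_ppb=spec.ambient_ppb,
                                chamber_id=chamber_id, deployment_date=ddate,
                            )
                        )
            control_mean = float(np.mean(cum_by_treatment[Treatment.CONTROL]))
            rep_efs = (
                [
                    (c - control_mean) / n_applied * 100.0
                    for c in cum_by_treatment[Treatment.URINE]
                ]
                if n_applied is not None else []
            )
            site_ef_components[cond.value] = {
                "emitted": float(np.mean(cum_by_treatment[Treatment.URINE])),
                "control": control_mean,
                "ef": float(np.mean(rep_efs)) if rep_efs else math.nan,
            }
        for cond_name, comp in site_ef_components.items():
            truth_ef_rows.append(
                {
                    "site": site_id, "condition": cond_name,
                    "true_ef_percent": comp["ef"],
                    "true_emitted_kg_ha": comp["emitted"],
                    "true_control_kg_ha": comp["control"],
                    "n_applied_kg_ha": n_applied if n_applied is not None else math.nan,
                }
            )

    ds = CampaignDataset(
        units=units, series=series, urine=urine, weather=weather,
        sites=sites_meta, geometry=geometry,
    )
    truth = GroundTruth(
        fluxes=pd.DataFrame(truth_flux_rows),
        cumulative=pd.DataFrame(truth_cum_rows),
        ef=pd.DataFrame(truth_ef_rows),
        condition_multipliers={k: v for k, v in spec.condition_multipliers},
    )
    return ds, truth
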