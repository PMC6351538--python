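"""Domain types for a multi-site urine-patch N2O chamber campaign.

The campaign is a set of experimental units (one static chamber per unit)
arranged as sites x pasture condition (LVC/AVC) x treatment (urine/control)
x replicate.  Each unit yields one headspace concentration series per
sampling day; sites carry a urine-application record, daily weather, and
soil metadata.

Constructors here are deliberately permissive about *data* invariants
(monotone minutes, physical ranges, design completeness): a dirty dataset
must be constructible so that :func:`patchflux.io.validate_campaign` can
enumerate every violation instead of dying on the first one.  Hard
structural errors (negative chamber height, mismatched list lengths) raise
immediately because nothing downstream can be computed from them.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class PastureCondition(str, Enum):
    """Vegetative-cover class: low (<70% soil cover) or adequate (>70%)."""

    LVC = "LVC"
    AVC = "AVC"


class Treatment(str, Enum):
    URINE = "urine"
    CONTROL = "control"


class QualityFlag(str, Enum):
    """Per-chamber regression quality flag; flags never drop data."""

    OK = "ok"
    LOW_R2 = "low_r2"
    CONSTANT = "constant"
    TOO_FEW_POINTS = "too_few_points"


@dataclass(frozen=True)
class ChamberGeometry:
    """Cylindrical static-chamber geometry.

    Parameters
    ----------
    height : float
        Chamber height above the soil surface, m.
    internal_diameter : float
        Internal diameter of the cylinder, m.
    """

    height: float
    internal_diameter: float

    def __post_init__(self) -> None:
        if not (self.height > 0):
            raise ValueError(f"chamber height must be > 0, got {self.height}")
        if not (self.internal_diameter > 0):
            raise ValueError(
                f"chamber internal_diameter must be > 0, got {self.internal_diameter}"
            )

    @property
    def area(self) -> float:
        """Soil footprint area, m^2."""
        return math.pi * (self.internal_diameter / 2.0) ** 2

    @property
    def volume(self) -> float:
        """Headspace volume, m^3."""
        return self.area * self.height

    @property
    def headspace_ratio(self) -> float:
        """Headspace volume per unit area V/A, m.  Equals the height."""
        return self.height


@dataclass(frozen=True)
class ExperimentalUnit:
    site_id: str
    pasture_condition: PastureCondition
    treatment: Treatment
    replicate: int
    chamber_id: str

    @property
    def key(self) -> tuple:
        return (self.site_id, self.pasture_condition, self.treatment, self.replicate)


@dataclass
class ConcentrationSeries:
    """One chamber deployment: timed headspace N2O mole fractions.

    minutes are elapsed minutes since chamber closure (first element 0 in a
    clean deployment); concentrations are N2O mole fractions in ppb
    (nmol mol^-1).  Temperature and pressure are single per-deployment
    values used for the ideal-gas conversion.
    """

    chamber_id: str
    deployment_date: _dt.date
    minutes: Sequence[float]
    concentrations: Sequence[float]
    chamber_temperature: float  # deg C
    pressure: float  # kPa

    def __post_init__(self) -> None:
        if len(self.minutes) != len(self.concentrations):
            raise ValueError(
                f"chamber {self.chamber_id} {self.deployment_date}: "
                f"{len(self.minutes)} minutes vs {len(self.concentrations)} concentrations"
            )

    @property
    def n_points(self) -> int:
        return len(self.minutes)

    def violations(self) -> list[str]:
        """Data-invariant violations of this deployment (empty when clean)."""
        where = f"series chamber={self.chamber_id} date={self.deployment_date}"
        out: list[str] = []
        m = list(self.minutes)
        if self.n_points < 3:
            out.append(f"{where}: fewer than 3 time points ({self.n_points})")
        if m and m[0] != 0:
            out.append(f"{where}: first minute is {m[0]}, expected 0")
        if any(b <= a for a, b in zip(m, m[1:])):
            out.append(f"{where}: non-increasing minutes {m}")
        if any(c < 0 for c in self.concentrations):
            out.append(f"{where}: negative concentration")
        if not (self.chamber_temperature > -40):
            out.append(f"{where}: temperature {self.chamber_temperature} degC out of range")
        if not (50 < self.pressure < 110):
            out.append(f"{where}: pressure {self.pressure} kPa outside (50, 110)")
        return out


@dataclass
class UrineApplication:
    """Per-site urine application.

    N_applied may be given directly (kg N ha^-1) or derived from volume and
    urine N concentration over the wetted area.  A missing N concentration
    with no direct N_applied leaves the site's emission factor undefined —
    not zero.
    """

    site_id: str
    application_date: _dt.date
    volume: Optional[float] = None  # L per chamber base
    urine_n_concentration: Optional[float] = None  # g N L^-1
    applied_area: Optional[float] = None  # m^2; defaults to chamber base area
    n_applied: Optional[float] = None  # kg N ha^-1

    def violations(self) -> list[str]:
        where = f"urine site={self.site_id}"
        out: list[str] = []
        if self.n_applied is not None and not (self.n_applied > 0):
            out.append(f"{where}: n_applied must be > 0 when present, got {self.n_applied}")
        return out


@dataclass
class WeatherSeries:
    site_id: str
    dates: Sequence[_dt.date]
    rainfall: Sequence[float]  # mm d^-1
    mean_air_temperature: Sequence[float]  # deg C

    def __post_init__(self) -> None:
        n = len(self.dates)
        if len(self.rainfall) != n or len(self.mean_air_temperature) != n:
            raise ValueError(f"weather site={self.site_id}: ragged columns")

    def violations(self) -> list[str]:
        where = f"weather site={self.site_id}"
        out: list[str] = []
        if any(r < 0 for r in self.rainfall):
            out.append(f"{where}: negative rainfall")
        d = list(self.dates)
        if len(set(d)) != len(d):
            out.append(f"{where}: duplicate dates")
        if any(b <= a for a, b in zip(d, d[1:])):
            out.append(f"{where}: dates not strictly ordered")
        return out

    def total_rainfall(self, start: _dt.date, end: _dt.date) -> float:
        """Total rainfall (mm) on dates in [start, end]."""
        return float(sum(r for d, r in zip(self.dates, self.rainfall) if start <= d <= end))


@dataclass
class SiteMetadata:
    site_id: str
    country: Optional[str] = None
    location_name: Optional[str] = None
    texture_class: Optional[str] = None
    pH: Optional[float] = None
    bulk_density: Optional[float] = None  # g cm^-3
    SOC: Optional[float] = None  # %
    SON: Optional[float] = None  # %

    def violations(self) -> list[str]:
        where = f"site={self.site_id}"
        out: list[str] = []
        if self.pH is not None and not (3 < self.pH < 11):
            out.append(f"{where}: pH {self.pH} outside (3, 11)")
        if self.bulk_density is not None and not (0.3 < self.bulk_density < 2.2):
            out.append(f"{where}: bulk density {self.bulk_density} outside (0.3, 2.2)")
        return out


@dataclass
class CampaignDataset:
    """The full campaign: design, gas series, urine, weather, soil, geometry."""

    units: list[ExperimentalUnit]
    series: list[ConcentrationSeries]
    urine: list[UrineApplication]
    weather: list[WeatherSeries]
    sites: list[SiteMetadata] = field(default_factory=list)
    geometry: ChamberGeometry = field(
        default_factory=lambda: ChamberGeometry(height=0.10, internal_diameter=0.25)
    )

    def unit_for_chamber(self, chamber_id: str) -> ExperimentalUnit:
        for u in self.units:
            if u.chamber_id == chamber_id:
                return u
        raise KeyError(f"no experimental unit for chamber {chamber_id!r}")

    @property
    def chamber_map(self) -> dict[str, ExperimentalUnit]:
        return {u.chamber_id: u for u in self.units}

    def urine_for_site(self, site_id: str) -> Optional[UrineApplication]:
        for a in self.urine:
            if a.site_id == site_id:
                return a
        return None

    def weather_for_site(self, site_id: str) -> Optional[WeatherSeries]:
        for w in self.weather:
            if w.site_id == site_id:
                return w
        return None

    @property
    def site_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for u in self.units:
            seen.setdefault(u.site_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# Result types


@dataclass(frozen=True)
class SlopeFit:
    """OLS line of headspace concentration (ppb) on elapsed minutes."""

    slope: float  # ppb min^-1
    intercept: float  # ppb
    r_squared: float  # NaN when concentration variance is zero
    n_points: int


@dataclass(frozen=True)
class FluxEstimate:
    chamber_id: str
    date: _dt.date
    flux: float  # mg N2O-N m^-2 d^-1; negative allowed
    slope_fit: SlopeFit
    quality_flag: QualityFlag


@dataclass(frozen=True)
class EmissionSeries:
    """Daily fluxes for one unit on the elapsed-day axis (day 0 = urine application)."""

    unit: ExperimentalUnit
    days: tuple[float, ...]
    fluxes: tuple[float, ...]  # mg N2O-N m^-2 d^-1

    def __post_init__(self) -> None:
        if len(self.days) != len(self.fluxes):
            raise ValueError("days and fluxes must align")


@dataclass(frozen=True)
class CumulativeEmission:
    unit: ExperimentalUnit
    value: float  # kg N2O-N ha^-1
    window: tuple[float, float]  # (first day, last day)


@dataclass(frozen=True)
class EmissionFactor:
    """Percent of applied urine-N emitted as N2O-N, control-corrected.

    value = (emitted - control) / n_applied * 100.  None when n_applied is
    missing (emission factor undefined, never coerced to zero).
    """

    site_id: str
    pasture_condition: PastureCondition
    value: Optional[float]
    emitted: float  # kg N2O-N ha^-1
    control: float  # kg N2O-N ha^-1
    n_applied: Optional[float]  # kg N ha^-1
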