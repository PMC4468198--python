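"""Annual pest risk indices and host-parasitoid synchrony.

Three indices summarise what a year of temperatures at a location means
for an insect population:

* ERI (establishment risk index, in [0, 1]) — the annual mean of the
  product of daily immature-stage survivals, i.e. how well the life
  cycle survives the local temperature regime;
* GI (generation index, generations/year) — 365 divided by the mean
  generation time of cohorts launched on the first day of each month;
* AI (activity index) — log10 of the factor by which the population
  would multiply over the year, the annual sum of daily intrinsic rates
  in log10 units.

ERI and AI are driven by daily-mean temperatures (index lookups); GI
runs the full stochastic cohort simulator.  Host-parasitoid synchrony
is the signed difference of establishment indices at the same places.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .lifetable import CohortConfig, RmProfile, simulate_cohort
from .phenology import SpeciesModel, stage_mortality
from .weather import WeatherSeries, _MONTH_STARTS

__all__ = [
    "RiskIndexSet",
    "FiniteRateSeries",
    "establishment_index",
    "generation_index",
    "activity_index",
    "finite_rate_series",
    "station_indices",
    "synchrony",
    "AI_RM_FLOOR",
]

#: floor (1/day) applied to the interpolated r_m in AI sums so lethal
#: days cannot drive the annual log-growth to -infinity
AI_RM_FLOOR = -0.1


@dataclass(frozen=True)
class RiskIndexSet:
    """The three annual indices at one station."""

    station_id: str
    lon: float
    lat: float
    alt: float
    eri: float
    gi: float
    ai: float

    def __post_init__(self):
        if not 0.0 <= self.eri <= 1.0:
            raise ValueError("ERI must lie in [0, 1]")
        if self.gi < 0.0:
            raise ValueError("GI must be non-negative")
        if not np.isfinite(self.ai):
            raise ValueError("AI must be finite")


@dataclass(frozen=True)
class FiniteRateSeries:
    """Daily finite rate of increase lambda_day over one calendar year."""

    day_of_year: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        if len(self.lam) != 365:
            raise ValueError("need 365 daily values")
        if np.any(np.asarray(self.lam) <= 0.0):
            raise ValueError("lambda_day must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.day_of_year, "lambda": self.lam})


def establishment_index(sp: SpeciesModel, w: WeatherSeries) -> float:
    """ERI: annual mean of the daily product of immature-stage survivals.

    ERI = (1/365) * sum_days prod_stages (1 - m_stage(T_mean(day))).
    """
    dm = w.daily_means()
    surv = np.ones(365)
    for stage in sp.stages:
        surv *= 1.0 - stage_mortality(dm, stage.mortality)
    return float(surv.mean())


def generation_index(sp: SpeciesModel, w: WeatherSeries,
                     cfg: CohortConfig) -> float:
    """GI: 365 over the mean generation time of 12 monthly cohort launches.

    Cohorts are launched on the first day of each calendar month (the
    weather wraps past day 365); launches whose cohort goes extinct are
    excluded from the mean.  Returns 0 when every launch is extinct.
    Launch seeds are derived as cfg.seed + launch index so the whole
    index is reproducible from one seed.
    """
    gen_times = []
    for i, day in enumerate(_MONTH_STARTS):
        launch_cfg = CohortConfig(
            n_individuals=cfg.n_individuals,
            seed=cfg.seed + i,
            start_day=int(day),
            driver=cfg.driver,
        )
        res = simulate_cohort(sp, w, launch_cfg)
        if not res.extinct and res.generation_time is not None:
            gen_times.append(res.generation_time)
    if not gen_times:
        return 0.0
    return float(365.0 / np.mean(gen_times))


def activity_index(sp: SpeciesModel, w: WeatherSeries, rm_map: RmProfile,
                   rm_floor: float = AI_RM_FLOOR) -> float:
    """AI: annual population log10-growth under the local temperatures.

    AI = (1/ln 10) * sum_days max(rm_floor, rm(T_mean(day))).
    """
    rm = np.maximum(rm_floor, rm_map(w.daily_means()))
    return float(rm.sum() / np.log(10.0))


def finite_rate_series(sp: SpeciesModel, w: WeatherSeries, rm_map: RmProfile,
                       rm_floor: float = AI_RM_FLOOR) -> FiniteRateSeries:
    """Daily finite rate lambda_day = exp(max(rm_floor, rm(T_mean(day)))).

    Summing log10 lambda_day over the year reproduces the activity
    index exactly.
    """
    rm = np.maximum(rm_floor, rm_map(w.daily_means()))
    return FiniteRateSeries(np.arange(1, 366), np.exp(rm))


def station_indices(sp: SpeciesModel, w: WeatherSeries, rm_map: RmProfile,
                    cfg: CohortConfig,
                    rm_floor: float = AI_RM_FLOOR) -> RiskIndexSet:
    """All three indices at one station, bundled with its metadata."""
    return RiskIndexSet(
        station_id=w.station_id, lon=w.lon, lat=w.lat, alt=w.alt,
        eri=establishment_index(sp, w),
        gi=generation_index(sp, w, cfg),
        ai=activity_index(sp, w, rm_map, rm_floor),
    )


def synchrony(host, parasitoid):
    """Host ERI minus parasitoid ERI, elementwise.

    Accepts two RiskIndexSet objects (same station), two equal-length
    sequences of them (stations matched by id), or two index grids
    (see :mod:`phenorisk.mapping`; geometry must match).  Negative
    values mean the parasitoid's establishment exceeds the host's.
    """
    from .mapping import Grid, grid_difference

    if isinstance(host, Grid) or isinstance(parasitoid, Grid):
        if not (isinstance(host, Grid) and isinstance(parasitoid, Grid)):
            raise TypeError("synchrony operands must have the same shape")
        return grid_difference(host, parasitoid)
    if isinstance(host, RiskIndexSet):
        if host.station_id != parasitoid.station_id:
            raise ValueError("synchrony requires matching stations")
        return host.eri - parasitoid.eri
    host, parasitoid = list(host), list(parasitoid)
    if [h.station_id for h in host] != [p.station_id for p in parasitoid]:
        raise ValueError("synchrony requires matching station sequences")
    return np.array([h.eri - p.eri for h, p in zip(host, parasitoid)])
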