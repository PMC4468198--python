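"""Stochastic cohort life-table simulation under fluctuating temperature.

A cohort of eggs is laid at midnight on a start day and followed through
egg, larva and pupa by rate summation: each individual accumulates
temperature-dependent development (Logan rate x time step) divided by an
individual stage-specific variability multiplier until the sum reaches 1.
Whole-stage mortality m(T) is converted to a per-step survival
probability (1 - m)^(fraction of stage completed that step), so at
constant temperature an individual that completes the stage has survived
it with probability exactly 1 - m(T).  Surviving adults are treated as
females of a female-based life table: they age deterministically by
daily senescence-rate summation and deposit ``total_fecundity(T) *
sex_ratio`` female eggs over normalised adult age following the gamma
oviposition profile.

From the resulting daily l_x (survivorship) / m_x (female eggs per
female) schedule the five classical life-table parameters are derived:
net reproduction R0 = sum l_x m_x, mean generation time
T = sum x l_x m_x / R0, the intrinsic rate of increase r_m solving the
Euler-Lotka renewal equation sum e^(-r x) l_x m_x = 1, the finite rate
of increase lambda = e^(r_m) and the doubling time ln 2 / r_m.

The simulation is driven either hourly (24 cosine-interpolated steps per
day, the default) or on daily means; the weather year wraps cyclically.
Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gamma as _gamma_dist

from .phenology import (
    SpeciesModel,
    StinnerParams,
    adult_longevity,
    development_rate,
    sample_dev_multiplier,
    senescence_rate,
    stage_mortality,
    total_fecundity,
)
from .weather import PEAK_HOUR, WeatherSeries

__all__ = [
    "CohortConfig",
    "LifeTableResult",
    "simulate_cohort",
    "solve_euler_lotka",
    "lifetable_at_constant",
    "constant_weather",
    "RmProfile",
    "rm_profile",
]

#: simulation horizon (days); individuals still immature at the horizon
#: are censored as dead without reproducing
HORIZON_DAYS = 4 * 365

#: hard cap on adult lifespan (days) when the senescence rate vanishes
MAX_ADULT_DAYS = 400

#: guard against log(0) when a step's mortality reaches 1
_MORT_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-simulation settings.  The seed is mandatory."""

    n_individuals: int = 2000
    seed: int = 0
    start_day: int = 1
    driver: Literal["hourly", "daily_mean"] = "hourly"

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be at least 2")
        if not 1 <= self.start_day <= 365:
            raise ValueError("start_day must be in 1..365")
        if self.driver not in ("hourly", "daily_mean"):
            raise ValueError("driver must be 'hourly' or 'daily_mean'")


@dataclass
class LifeTableResult:
    """Life-table parameters extracted from one simulated cohort."""

    generation_time: Optional[float]  # T, days
    net_reproduction: float           # R0
    intrinsic_rate: Optional[float]   # rm, 1/day (None if undefined)
    finite_rate: Optional[float]      # lambda = e^rm
    doubling_time: Optional[float]    # ln2/rm (None if rm <= 0)
    stage_dev_time: dict              # mean days per immature stage
    stage_survival: dict              # fraction surviving each stage
    lx_mx: pd.DataFrame               # columns: age, lx, mx
    extinct: bool = False


def _tile_days(start_day: int, n_days: int) -> np.ndarray:
    """Day-of-year (1..365) for ``n_days`` consecutive days, wrapping."""
    return (start_day - 1 + np.arange(n_days)) % 365 + 1


def _step_temperatures(w: WeatherSeries, start_day: int, n_days: int,
                       driver: str) -> tuple[np.ndarray, int]:
    """Per-step temperatures and steps/day for the simulation timeline."""
    doy = _tile_days(start_day, n_days)
    tmin = w.tmin[doy - 1]
    tmax = w.tmax[doy - 1]
    mid = 0.5 * (tmax + tmin)
    if driver == "daily_mean":
        return mid, 1
    amp = 0.5 * (tmax - tmin)
    hours = np.arange(24)
    wave = np.cos(2.0 * np.pi * (hours - PEAK_HOUR) / 24.0)
    temps = mid[:, None] + amp[:, None] * wave[None, :]
    return temps.ravel(), 24


def solve_euler_lotka(ages, lx_mx) -> Optional[float]:
    """Solve sum e^(-r x) l_x m_x = 1 for the intrinsic rate r.

    Returns None when the schedule carries no reproduction (R0 <= 0).
    Uses a safeguarded bracketing solve on [-1, 1] 1/day, widened if the
    root falls outside; the residual of the returned root is < 1e-10.
    """
    x = np.asarray(ages, dtype=float)
    v = np.asarray(lx_mx, dtype=float)
    keep = v > 0.0
    x, v = x[keep], v[keep]
    r0 = v.sum()
    if r0 <= 0.0:
        return None
    if np.all(x == 0.0):
        raise ValueError("reproduction at age zero: Euler-Lotka undefined")

    def f(r):
        # overflow at extreme bracket probes saturates to +inf, which the
        # sign checks below handle correctly
        with np.errstate(over="ignore"):
            return np.exp(-r * x) @ v - 1.0

    lo, hi = -1.0, 1.0
    for _ in range(60):  # f is strictly decreasing in r
        if f(lo) > 0.0 >= f(hi):
            break
        if f(lo) <= 0.0:
            lo *= 2.0
        if f(hi) > 0.0:
            hi *= 2.0
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))


def simulate_cohort(sp: SpeciesModel, w: WeatherSeries,
                    cfg: CohortConfig) -> LifeTableResult:
    """Simulate one cohort and extract its life-table parameters.

    Extinction (no female egg deposited) is data, not an exception: the
    result carries R0 = 0 with ``extinct=True`` and the rate parameters
    set to None.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    temps, k = _step_temperatures(w, cfg.start_day, HORIZON_DAYS, cfg.driver)
    dt = 1.0 / k
    n_steps = temps.size

    # Per-stage cumulative development and log-survival integrals.
    # R[j] = integral of rate dt over steps < j;
    # G[j] = integral of rate*ln(1-m) dt over steps < j  (non-increasing).
    R_cum, G_cum = {}, {}
    for stage in sp.stages:
        rate = development_rate(temps, stage.dev_rate)
        m = np.minimum(stage_mortality(temps, stage.mortality), _MORT_CLIP)
        R_cum[stage.name] = np.concatenate(([0.0], np.cumsum(rate * dt)))
        G_cum[stage.name] = np.concatenate(([0.0], np.cumsum(rate * np.log1p(-m) * dt)))

    alive = np.ones(n, dtype=bool)
    pos = np.zeros(n, dtype=np.int64)        # current step index
    death_age = np.full(n, np.nan)           # days from oviposition
    stage_dev_time, stage_survival = {}, {}

    for stage in sp.stages:
        R, G = R_cum[stage.name], G_cum[stage.name]
        mult = sample_dev_multiplier(rng.uniform(1e-12, 1.0 - 1e-12, size=n),
                                     stage.dev_var)
        u = rng.uniform(1e-300, 1.0, size=n)

        idx = np.where(alive)[0]
        start = pos[idx]
        # tiny relative slack so exactly-divisible durations are not pushed
        # one step past a cumsum round-off
        target = R[start] + mult[idx] * (1.0 - 1e-9)
        done = np.searchsorted(R, target, side="left")
        complete = done <= n_steps
        done = np.minimum(done, n_steps)

        log_surv = (G[done] - G[start]) / mult[idx]
        survives = complete & (np.log(u[idx]) <= log_surv)

        # death step for non-survivors: first step where cumulative
        # log-survival falls below ln u
        dies = ~survives
        if np.any(dies):
            gi = np.where(dies)[0]
            thresh = G[start[gi]] + mult[idx[gi]] * np.log(u[idx[gi]])
            dstep = np.searchsorted(-G, -thresh, side="left")
            dstep = np.clip(np.maximum(dstep, start[gi] + 1), None, n_steps)
            death_age[idx[gi]] = dstep * dt

        dev_steps = (done - start)[survives]
        stage_dev_time[stage.name] = (
            float(np.mean(dev_steps) * dt) if dev_steps.size else float("nan"))
        stage_survival[stage.name] = float(np.mean(survives)) if idx.size else 0.0

        pos[idx[survives]] = done[survives]
        alive[idx] = survives

    # ----- adults (deterministic females) ---------------------------------
    doy = _tile_days(cfg.start_day, HORIZON_DAYS)
    dmeans = 0.5 * (w.tmin[doy - 1] + w.tmax[doy - 1])
    if isinstance(sp.adult_longevity, StinnerParams):
        sen_rate = 1.0 / adult_longevity(dmeans, sp.adult_longevity)
    else:
        sen_rate = senescence_rate(dmeans, sp.adult_longevity)
    sen_rate = np.maximum(sen_rate, 1.0 / MAX_ADULT_DAYS)
    A_cum = np.concatenate(([0.0], np.cumsum(sen_rate)))
    dm_cum = np.concatenate(([0.0], np.cumsum(dmeans)))

    adult_idx = np.where(alive)[0]
    eggs_at_age = np.zeros(HORIZON_DAYS, dtype=float)
    gdist = _gamma_dist(sp.fecundity.gamma_shape, scale=sp.fecundity.gamma_scale)
    gnorm = gdist.cdf(1.0)

    for i in adult_idx:
        e_day = int(pos[i] // k)          # age (whole days) at emergence
        if e_day >= HORIZON_DAYS - 1:
            death_age[i] = float(HORIZON_DAYS)
            continue
        # rate-summation of the daily senescence hazard until it reaches 1
        target = A_cum[e_day] + 1.0
        j = int(np.searchsorted(A_cum, target, side="left")) - 1
        j = min(j, HORIZON_DAYS - 1)
        lifespan = (j - e_day) + (target - A_cum[j]) / sen_rate[j]
        lifespan = float(min(lifespan, MAX_ADULT_DAYS, HORIZON_DAYS - 1 - e_day))
        if lifespan <= 0.0:
            lifespan = 1e-9
        death_age[i] = e_day + lifespan

        n_adult_days = max(int(np.ceil(lifespan)), 1)
        last = min(e_day + n_adult_days, HORIZON_DAYS)
        t_adult = (dm_cum[last] - dm_cum[e_day]) / (last - e_day)
        fem_eggs = total_fecundity(t_adult, sp.fecundity) * sp.sex_ratio
        if fem_eggs <= 0.0:
            continue
        edges = np.minimum(np.arange(n_adult_days + 1) / lifespan, 1.0)
        frac = np.diff(gdist.cdf(edges)) / gnorm
        ages = e_day + np.arange(n_adult_days)
        np.add.at(eggs_at_age, ages[ages < HORIZON_DAYS],
                  fem_eggs * frac[ages < HORIZON_DAYS])

    # ----- l_x / m_x table and parameters ---------------------------------
    death_age = np.where(np.isnan(death_age), float(HORIZON_DAYS), death_age)
    max_age = min(int(np.ceil(death_age.max())) + 1, HORIZON_DAYS)
    ages = np.arange(max_age)
    n_alive = (death_age[None, :] > ages[:, None]).sum(axis=1)
    lx = n_alive / n
    mx = np.zeros(max_age)
    laid = eggs_at_age[:max_age]
    nz = n_alive > 0
    mx[nz] = laid[nz] / n_alive[nz]

    lxmx = lx * mx
    r0 = float(lxmx.sum())
    table = pd.DataFrame({"age": ages, "lx": lx, "mx": mx})

    if r0 <= 0.0:
        return LifeTableResult(None, 0.0, None, None, None,
                               stage_dev_time, stage_survival, table,
                               extinct=True)

    gen_time = float((ages * lxmx).sum() / r0)
    rm = solve_euler_lotka(ages, lxmx)
    lam = float(np.exp(rm)) if rm is not None else None
    dt_ = float(np.log(2.0) / rm) if rm is not None and rm > 0 else None
    return LifeTableResult(gen_time, r0, rm, lam, dt_,
                           stage_dev_time, stage_survival, table)


def constant_weather(t: float, station_id: str = "const",
                     alt: float = 0.0) -> WeatherSeries:
    """A synthetic 365-day series with tmin = tmax = t every day."""
    temps = np.full(365, float(t))
    return WeatherSeries(station_id, 0.0, 0.0, alt, temps, temps)


def lifetable_at_constant(sp: SpeciesModel, t: float,
                          cfg: CohortConfig) -> LifeTableResult:
    """Cohort simulation at a constant temperature ``t`` (degC)."""
    return simulate_cohort(sp, constant_weather(t), cfg)


class RmProfile:
    """Piecewise-linear map from temperature to intrinsic rate r_m.

    Built from constant-temperature cohort simulations at the grid
    nodes; non-viable temperatures take the configurable extinction
    floor.  Queries outside the grid hull are clamped (with a warning).
    """

    def __init__(self, t_grid: np.ndarray, rm_values: np.ndarray,
                 rm_floor: float):
        self.t_grid = np.asarray(t_grid, dtype=float)
        self.rm_values = np.asarray(rm_values, dtype=float)
        self.rm_floor = float(rm_floor)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_grid[0]) or np.any(t > self.t_grid[-1]):
            warnings.warn("rm_profile query outside grid hull; clamped",
                          stacklevel=2)
        out = np.interp(t, self.t_grid, self.rm_values)
        return float(out) if out.ndim == 0 else out


def rm_profile(sp: SpeciesModel, t_grid: Sequence[float], cfg: CohortConfig,
               rm_floor: float = -0.5) -> RmProfile:
    """Evaluate r_m on a temperature grid by constant-T simulation.

    The grid must be strictly increasing and should span the weather
    range the profile will be queried on.  Extinct nodes (and nodes with
    rm below the floor) take ``rm_floor`` (default -0.5/day).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 nodes")
    rms = np.empty(t_grid.size)
    for i, t in enumerate(t_grid):
        res = lifetable_at_constant(sp, float(t), cfg)
        rm = res.intrinsic_rate
        rms[i] = rm_floor if rm is None else max(rm, rm_floor)
    return RmProfile(t_grid, rms, rm_floor)
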