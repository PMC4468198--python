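"""Seeded generators for every input the pipeline consumes.

The field inputs such an analysis normally requires — weather-station records along two East African
altitudinal transects, an SRTM elevation model, species phenology
parameters estimated from laboratory life tables, downscaled warming
scenarios and survey-derived zone losses — are emulated here by pure
functions of a spec plus a seed:

* :func:`make_transect` builds a 6-station altitudinal transect
  (700-1800 m by default) with daily temperatures following an
  altitude lapse, a single annual harmonic and Gaussian noise, plus a
  one-sided synthetic mountain DEM containing the stations;
* :func:`make_species` ships four canonical phenology parameter sets
  named for the ecological roles in the system (lowland host ~ a
  warm-adapted stem borer, highland host ~ a cool-adapted stem borer,
  and their faster-developing larval parasitoids);
* :func:`make_scenario` produces monthly warming deltas with a chosen
  annual mean and seasonal half-range (default 1.45 +/- 0.45 degC,
  spanning 1.0-1.9);
* :func:`make_observed_losses` fabricates zone-level percent losses
  from a known linear index->loss relation plus noise.

Everything is bit-reproducible from its seed.  The species profiles are
qualitative emulations of the real species' thermal contrasts (warm vs
cool optima, parasitoids completing more generations than hosts), with
no claim of parameter fidelity to any laboratory estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mapping import Grid, write_ascii_grid
from .phenology import (
    DevVarParams,
    FecundityParams,
    HilbertLoganParams,
    LoganParams,
    MortalityParams,
    SpeciesModel,
    StageModel,
    StinnerParams,
    save_species,
)
from .weather import (
    ScenarioDelta,
    WeatherSeries,
    write_scenario_csv,
    write_weather_csv,
)

__all__ = [
    "TransectSpec",
    "make_transect",
    "make_species",
    "make_scenario",
    "make_observed_losses",
    "write_demo_fixture",
    "SPECIES_PROFILES",
]

#: day of year of the warm seasonal peak (mid-February, tropical SE Africa)
SEASONAL_PHASE_DAY = 46


@dataclass(frozen=True)
class TransectSpec:
    """Construction parameters of a synthetic altitudinal transect."""

    n_stations: int = 6
    alt_range: tuple = (700.0, 1800.0)
    lapse_rate: float = -6.5          # degC per km of altitude
    base_tmean: float = 28.0          # annual-mean temperature at sea level
    seasonal_amplitude: float = 2.0   # degC, annual harmonic
    diurnal_range: float = 10.0       # tmax - tmin, degC
    noise_sd: float = 1.0             # daily Gaussian noise, degC
    seed: int = 0
    second_harmonic_amplitude: float = 0.0  # optional semi-annual harmonic

    def __post_init__(self):
        if self.n_stations < 2:
            raise ValueError("need at least 2 stations")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.alt_range[1] > self.alt_range[0]:
            raise ValueError("alt_range must be increasing")


# --- DEM construction: a one-sided mountain slope ------------------------

_DEM_NCOLS = 48
_DEM_NROWS = 36
_DEM_CELLSIZE = 500.0  # metres
_DEM_NODATA = -9999.0


def _dem_elevation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Elevation (m) of the synthetic slope at planar coords (x, y).

    Monotone and mildly convex in x (west-to-east rise), with a gentle
    sinusoidal ridge in y so station layouts are never collinear.
    """
    width = _DEM_NCOLS * _DEM_CELLSIZE
    depth = _DEM_NROWS * _DEM_CELLSIZE
    frac = np.clip(x / width, 0.0, 1.0)
    return 550.0 + 1500.0 * frac ** 1.3 + 25.0 * np.sin(2.0 * np.pi * y / depth)


def _make_dem() -> Grid:
    g = Grid(_DEM_NCOLS, _DEM_NROWS, 0.0, 0.0, _DEM_CELLSIZE, _DEM_NODATA,
             np.zeros((_DEM_NROWS, _DEM_NCOLS)))
    gx, gy = g.cell_centers()
    return g.copy_with(_dem_elevation(gx, gy))


def make_transect(spec: TransectSpec):
    """Generate (weather series per station, DEM grid, station coords).

    Stations sit at altitudes evenly spaced over ``alt_range``; each is
    placed at the DEM cell whose elevation best matches its altitude on
    a staggered set of y positions (the match is within one cell's
    relief).  Daily mean temperature is

        base_tmean + lapse_rate * alt/1000
        + seasonal_amplitude * cos(2 pi (day - phase)/365) + noise,

    with tmin/tmax = tmean -/+ diurnal_range/2.  Coordinates are planar
    metres (stored in the series' lon/lat slots).
    """
    rng = np.random.default_rng(spec.seed)
    dem = _make_dem()
    depth = _DEM_NROWS * _DEM_CELLSIZE
    alts = np.linspace(spec.alt_range[0], spec.alt_range[1], spec.n_stations)

    coords = []
    for j, alt in enumerate(alts):
        yfrac = 0.2 + 0.6 * (j / max(spec.n_stations - 1, 1))
        y = yfrac * depth
        # bisect the monotone west-east profile for the matching x
        lo, hi = 0.0, _DEM_NCOLS * _DEM_CELLSIZE
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _dem_elevation(np.array(mid), np.array(y)) < alt:
                lo = mid
            else:
                hi = mid
        x = 0.5 * (lo + hi)
        # snap to the containing cell's centre
        col = int(np.clip(x // _DEM_CELLSIZE, 0, _DEM_NCOLS - 1))
        row_fb = int(np.clip(y // _DEM_CELLSIZE, 0, _DEM_NROWS - 1))
        cx = (col + 0.5) * _DEM_CELLSIZE
        cy = (row_fb + 0.5) * _DEM_CELLSIZE
        coords.append((cx, cy))

    days = np.arange(1, 366)
    seasonal = spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (days - SEASONAL_PHASE_DAY) / 365.0)
    if spec.second_harmonic_amplitude:
        seasonal = seasonal + spec.second_harmonic_amplitude * np.cos(
            4.0 * np.pi * (days - SEASONAL_PHASE_DAY) / 365.0)

    series = []
    half = spec.diurnal_range / 2.0
    for j, (alt, (cx, cy)) in enumerate(zip(alts, coords)):
        tmean = (spec.base_tmean + spec.lapse_rate * alt / 1000.0 + seasonal
                 + rng.normal(0.0, spec.noise_sd, size=365))
        series.append(
            WeatherSeries(f"st{j + 1:02d}", cx, cy, float(alt),
                          tmean - half, tmean + half)
        )
    return series, dem, coords


# --- species profiles ------------------------------------------------------

def _logan(t_dev: float, duration_days: float) -> LoganParams:
    """Logan parameters peaking near ``t_dev`` with 1/rate(t_dev) = duration."""
    rho, delta = 0.15, 3.0
    t_base, t_max = t_dev - 17.0, t_dev + 6.0
    bracket = (np.exp(rho * (t_dev - t_base))
               - np.exp(rho * (t_max - t_base) - (t_max - t_dev) / delta))
    return LoganParams(psi=1.0 / (duration_days * bracket), rho=rho,
                       t_base=t_base, t_max=t_max, delta=delta)


def _mortality(m_min: float, t_mort: float, curvature: float) -> MortalityParams:
    """Exponential-quadratic mortality with minimum ``m_min`` at ``t_mort``."""
    return MortalityParams(
        b0=float(np.log(m_min) + curvature * t_mort ** 2),
        b1=float(-2.0 * curvature * t_mort),
        b2=float(curvature),
    )


def _fecundity(f_max: float, t_fec: float, width: float) -> FecundityParams:
    """Quadratic fecundity peaking at ``t_fec``, zero at t_fec +/- width."""
    c2 = -f_max / width ** 2
    return FecundityParams(
        c0=float(f_max + c2 * t_fec ** 2),
        c1=float(-2.0 * c2 * t_fec),
        c2=float(c2),
        gamma_shape=2.0,
        gamma_scale=0.15,
    )


#: high-level traits per ecological role: development optimum, mortality
#: optimum, fecundity optimum (degC); stage durations at the development
#: optimum (days); peak fecundity (eggs) and quadratic half-width (degC);
#: adult-longevity family and parameters
SPECIES_PROFILES = {
    "lowland_host": dict(
        t_dev=30.0, t_mort=26.0, t_fec=28.0,
        durations=(6.0, 25.0, 9.0), f_max=300.0, f_width=12.0,
        adult=("stinner", dict(c_max=35.0, k1=-5.0, k2=0.16)),
    ),
    "highland_host": dict(
        t_dev=24.0, t_mort=17.0, t_fec=20.0,
        durations=(8.0, 35.0, 12.0), f_max=250.0, f_width=12.0,
        adult=("stinner", dict(c_max=45.0, k1=-5.0, k2=0.18)),
    ),
    "lowland_parasitoid": dict(
        t_dev=30.0, t_mort=25.0, t_fec=28.0,
        durations=(3.0, 8.0, 5.0), f_max=150.0, f_width=13.0,
        adult=("hilbert_logan",
               dict(psi=0.15, d=8.0, t_base=12.0, t_max=38.0, delta=5.0)),
    ),
    "highland_parasitoid": dict(
        t_dev=25.0, t_mort=18.0, t_fec=21.0,
        durations=(4.0, 10.0, 6.0), f_max=120.0, f_width=13.0,
        adult=("stinner", dict(c_max=30.0, k1=-5.0, k2=0.20)),
    ),
}

_STAGE_MORT = {  # (minimum mortality, exponent curvature) per stage
    "egg": (0.03, 0.012),
    "larva": (0.08, 0.015),
    "pupa": (0.04, 0.012),
}

_STAGE_DEVVAR = {  # variability family and slope per stage
    "egg": ("logit", 8.0),
    "larva": ("logit", 8.0),
    "pupa": ("cloglog", 8.0),
}


def make_species(profile: str, seed: int | None = None) -> SpeciesModel:
    """Canonical phenology parameter set for one ecological role.

    The four profiles contrast a warm thermal niche (lowland) with a
    cool one (highland) and give parasitoids markedly shorter immature
    development than their hosts.  The parameter values are fixed
    constants of the package; ``seed`` is accepted for interface
    uniformity and does not alter them.
    """
    if profile not in SPECIES_PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; choose from {sorted(SPECIES_PROFILES)}")
    p = SPECIES_PROFILES[profile]
    stages = []
    for name, dur in zip(("egg", "larva", "pupa"), p["durations"]):
        m_min, curv = _STAGE_MORT[name]
        family, beta = _STAGE_DEVVAR[name]
        stages.append(
            StageModel(
                name=name,
                dev_rate=_logan(p["t_dev"], dur),
                mortality=_mortality(m_min, p["t_mort"], curv),
                dev_var=DevVarParams(family=family, beta=beta),
            )
        )
    fam, kw = p["adult"]
    adult = StinnerParams(**kw) if fam == "stinner" else HilbertLoganParams(**kw)
    return SpeciesModel(
        species_name=profile,
        stages=stages,
        adult_longevity=adult,
        fecundity=_fecundity(p["f_max"], p["t_fec"], p["f_width"]),
        sex_ratio=0.5,
    )


def make_scenario(warming_c: float = 1.45, seasonal_skew: float = 0.45,
                  seed: int | None = None) -> ScenarioDelta:
    """Monthly warming deltas with mean ``warming_c``, half-range ``seasonal_skew``.

    The deltas follow one cosine over the 12 months (largest warming in
    September), so their mean is exactly ``warming_c`` and they span
    [warming_c - skew, warming_c + skew].  Applied equally to tmin and
    tmax.  Deterministic; ``seed`` is accepted for interface uniformity.
    """
    if not np.isfinite(warming_c):
        raise ValueError("warming_c must be finite")
    months = np.arange(12)
    deltas = warming_c + seasonal_skew * np.cos(2.0 * np.pi * (months - 8) / 12.0)
    return ScenarioDelta(tuple(deltas), tuple(deltas))


def make_observed_losses(true_beta0: float, true_beta1: float, ai_per_zone,
                         noise_sd: float, seed: int) -> np.ndarray:
    """Zone losses beta0 + beta1*AI + N(0, noise_sd), clamped at >= 0."""
    ai = np.asarray(ai_per_zone, dtype=float)
    if ai.size < 3:
        raise ValueError("need at least 3 zones")
    rng = np.random.default_rng(seed)
    losses = true_beta0 + true_beta1 * ai + rng.normal(0.0, noise_sd, size=ai.size)
    return np.maximum(losses, 0.0)


def write_demo_fixture(outdir, seed: int = 0, spec: TransectSpec | None = None):
    """Write the full demo-transect fixture into ``outdir``.

    Produces weather.csv, dem.asc, scenario.csv and one species YAML per
    profile; returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec if spec is not None else TransectSpec(seed=seed)
    series, dem, _ = make_transect(spec)
    paths = {}
    paths["weather"] = outdir / "weather.csv"
    write_weather_csv(series, paths["weather"])
    paths["dem"] = outdir / "dem.asc"
    write_ascii_grid(dem, paths["dem"])
    paths["scenario"] = outdir / "scenario.csv"
    write_scenario_csv(make_scenario(), paths["scenario"])
    for profile in SPECIES_PROFILES:
        paths[profile] = outdir / f"{profile}.yaml"
        save_species(make_species(profile, seed), paths[profile])
    return paths
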