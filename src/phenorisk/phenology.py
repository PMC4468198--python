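"""Temperature-response functions for insect phenology.

A species' life cycle is described by a set of closed-form temperature
responses, one family per biological process:

* development rate of each immature stage — Logan (type-I) model;
* immature stage mortality — second-order exponential polynomial,
  clamped to [0, 1];
* individual variation of development time — logit or complementary
  log-log quantile functions on log-normalised time (median multiplier
  fixed at 1 for the logit family);
* adult female longevity — three-parameter Stinner logistic, or a
  Hilbert–Logan senescence *rate* for species whose ageing accelerates
  sigmoidally with temperature;
* lifetime fecundity — quadratic polynomial in temperature, distributed
  over normalised adult age by a gamma profile.

Parameters are inputs (estimated elsewhere from laboratory life tables);
this module only evaluates the curves and validates parameter records.
Temperatures are degrees Celsius throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "LoganParams",
    "MortalityParams",
    "DevVarParams",
    "StinnerParams",
    "HilbertLoganParams",
    "FecundityParams",
    "StageModel",
    "SpeciesModel",
    "development_rate",
    "stage_mortality",
    "sample_dev_multiplier",
    "adult_longevity",
    "senescence_rate",
    "total_fecundity",
    "oviposition_fraction",
    "species_to_dict",
    "species_from_dict",
    "load_species",
    "save_species",
]

STAGE_NAMES = ("egg", "larva", "pupa")


def _require_finite(t, name: str = "temperature"):
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {t!r}")
    return arr


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoganParams:
    """Logan development-rate parameters.

    psi : scale (1/day); rho : rate coefficient (1/degC);
    t_base : lower reference temperature (degC); t_max : lethal maximum
    (degC); delta : width of the high-temperature decay (degC).
    """

    psi: float
    rho: float
    t_base: float
    t_max: float
    delta: float

    def __post_init__(self):
        if not (self.psi > 0 and self.rho > 0 and self.delta > 0):
            raise ValueError("psi, rho and delta must be positive")
        if not self.t_max > self.t_base:
            raise ValueError("t_max must exceed t_base")


@dataclass(frozen=True)
class MortalityParams:
    """Coefficients of the exponential-quadratic stage mortality curve."""

    b0: float
    b1: float
    b2: float


@dataclass(frozen=True)
class DevVarParams:
    """Development-time variability: quantile family and slope beta.

    The intercept is fixed at zero, so for the logit family the median
    multiplier is exactly 1 and ``beta`` alone controls the spread.
    """

    family: Literal["logit", "cloglog"]
    beta: float

    def __post_init__(self):
        if self.family not in ("logit", "cloglog"):
            raise ValueError(f"unknown variability family {self.family!r}")
        if not self.beta > 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class StinnerParams:
    """Three-parameter Stinner adult-longevity logistic."""

    c_max: float
    k1: float
    k2: float

    def __post_init__(self):
        if not self.c_max > 0:
            raise ValueError("c_max must be positive")


@dataclass(frozen=True)
class HilbertLoganParams:
    """Hilbert–Logan senescence-rate parameters (adult ageing)."""

    psi: float
    d: float
    t_base: float
    t_max: float
    delta: float

    def __post_init__(self):
        if not (self.psi > 0 and self.d > 0 and self.delta > 0):
            raise ValueError("psi, d and delta must be positive")
        if not self.t_max > self.t_base:
            raise ValueError("t_max must exceed t_base")


@dataclass(frozen=True)
class FecundityParams:
    """Quadratic lifetime fecundity plus a gamma oviposition-age profile."""

    c0: float
    c1: float
    c2: float
    gamma_shape: float
    gamma_scale: float

    def __post_init__(self):
        if not (self.gamma_shape > 0 and self.gamma_scale > 0):
            raise ValueError("gamma_shape and gamma_scale must be positive")


@dataclass(frozen=True)
class StageModel:
    """One immature stage: development rate, mortality and variability."""

    name: Literal["egg", "larva", "pupa"]
    dev_rate: LoganParams
    mortality: MortalityParams
    dev_var: DevVarParams

    def __post_init__(self):
        if self.name not in STAGE_NAMES:
            raise ValueError(f"stage name must be one of {STAGE_NAMES}")


AdultLongevity = Union[StinnerParams, HilbertLoganParams]


@dataclass(frozen=True)
class SpeciesModel:
    """Full thermal phenology parameterisation of one species."""

    species_name: str
    stages: Sequence[StageModel]
    adult_longevity: AdultLongevity
    fecundity: FecundityParams
    sex_ratio: float = 0.5

    def __post_init__(self):
        names = tuple(s.name for s in self.stages)
        if names != STAGE_NAMES:
            raise ValueError(
                f"stages must be exactly {STAGE_NAMES} in order, got {names}"
            )
        if not isinstance(self.adult_longevity, (StinnerParams, HilbertLoganParams)):
            raise TypeError("adult_longevity must be Stinner or Hilbert–Logan")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def stage(self):
        return {s.name: s for s in self.stages}


# ---------------------------------------------------------------------------
# Response functions
# ---------------------------------------------------------------------------

def development_rate(t, p: LoganParams):
    """Logan development rate (1/day) at temperature ``t`` (degC).

    r(T) = psi * [exp(rho (T - Tb)) - exp(rho (Tmax - Tb) - (Tmax - T)/delta)]

    clamped below at zero; zero for T <= t_base and T >= t_max.
    """
    t = _require_finite(t)
    rate = p.psi * (
        np.exp(p.rho * (t - p.t_base))
        - np.exp(p.rho * (p.t_max - p.t_base) - (p.t_max - t) / p.delta)
    )
    rate = np.where((t <= p.t_base) | (t >= p.t_max), 0.0, rate)
    rate = np.maximum(rate, 0.0)
    return float(rate) if rate.ndim == 0 else rate


def stage_mortality(t, p: MortalityParams):
    """Whole-stage mortality fraction min(1, exp(b0 + b1 T + b2 T^2))."""
    t = _require_finite(t)
    m = np.exp(p.b0 + p.b1 * t + p.b2 * t * t)
    m = np.minimum(m, 1.0)
    return float(m) if m.ndim == 0 else m


def sample_dev_multiplier(u, p: DevVarParams):
    """Development-time multiplier at uniform quantile ``u`` in (0, 1).

    Inverse CDF on log-normalised time with intercept 0:
    logit family  -> exp(logit(u) / beta); median exactly 1;
    cloglog family -> exp(ln(-ln(1 - u)) / beta).
    """
    arr = np.asarray(u, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("quantile u must lie strictly inside (0, 1)")
    if p.family == "logit":
        z = np.log(arr / (1.0 - arr))
    else:  # cloglog
        z = np.log(-np.log1p(-arr))
    out = np.exp(z / p.beta)
    return float(out) if out.ndim == 0 else out


def adult_longevity(t, p: StinnerParams):
    """Stinner adult longevity (days): c_max / (1 + exp(k1 + k2 T))."""
    t = _require_finite(t)
    out = p.c_max / (1.0 + np.exp(p.k1 + p.k2 * t))
    return float(out) if out.ndim == 0 else out


def senescence_rate(t, p: HilbertLoganParams):
    """Hilbert–Logan adult senescence rate (1/day).

    With t' = max(0, T - t_base):
    rate = psi * [t'^2 / (t'^2 + d^2) - exp(-(t_max - T)/delta)], clamped
    at zero.  Under constant temperature the adult lifespan is 1/rate.
    """
    t = _require_finite(t)
    tp = np.maximum(0.0, t - p.t_base)
    rate = p.psi * (tp * tp / (tp * tp + p.d * p.d) - np.exp(-(p.t_max - t) / p.delta))
    rate = np.maximum(rate, 0.0)
    return float(rate) if rate.ndim == 0 else rate


def total_fecundity(t, p: FecundityParams):
    """Lifetime eggs per female: max(0, c0 + c1 T + c2 T^2)."""
    t = _require_finite(t)
    f = np.maximum(0.0, p.c0 + p.c1 * t + p.c2 * t * t)
    return float(f) if f.ndim == 0 else f


def oviposition_fraction(a0: float, a1: float, p: FecundityParams) -> float:
    """Fraction of lifetime eggs laid in the normalised-age window (a0, a1].

    The gamma CDF is renormalised by its value at age 1 so the fractions
    over any partition of [0, 1] sum to exactly 1.
    """
    if not (0.0 <= a0 < a1 <= 1.0):
        raise ValueError(f"need 0 <= a0 < a1 <= 1, got ({a0}, {a1})")
    dist = _gamma_dist(p.gamma_shape, scale=p.gamma_scale)
    total = dist.cdf(1.0)
    if total <= 0.0:
        raise ValueError("degenerate gamma profile: CDF(1) is zero")
    return float((dist.cdf(a1) - dist.cdf(a0)) / total)


# ---------------------------------------------------------------------------
# Species parameter files (YAML, one document per species)
# ---------------------------------------------------------------------------

def _plain(record: dict) -> dict:
    """Coerce numpy scalars to plain Python types for serialisation."""
    return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in record.items()}


def species_to_dict(sp: SpeciesModel) -> dict:
    d = {
        "species_name": sp.species_name,
        "sex_ratio": float(sp.sex_ratio),
        "stages": {},
        "fecundity": _plain(vars(sp.fecundity)),
    }
    for s in sp.stages:
        d["stages"][s.name] = {
            "dev_rate": _plain(vars(s.dev_rate)),
            "mortality": _plain(vars(s.mortality)),
            "dev_var": {"family": s.dev_var.family, "beta": float(s.dev_var.beta)},
        }
    al = sp.adult_longevity
    if isinstance(al, StinnerParams):
        d["adult_longevity"] = {"family": "stinner", **_plain(vars(al))}
    else:
        d["adult_longevity"] = {"family": "hilbert_logan", **_plain(vars(al))}
    return d


def species_from_dict(d: dict) -> SpeciesModel:
    """Build and validate a SpeciesModel from a plain mapping.

    Raises ``ValueError`` on missing stages or malformed records, so this
    doubles as the schema validator for species parameter files.
    """
    try:
        stages_raw = d["stages"]
    except KeyError as e:
        raise ValueError("species document lacks a 'stages' mapping") from e
    missing = [n for n in STAGE_NAMES if n not in stages_raw]
    if missing:
        raise ValueError(f"species document missing stage(s): {missing}")
    stages = []
    for name in STAGE_NAMES:
        raw = stages_raw[name]
        try:
            stages.append(
                StageModel(
                    name=name,
                    dev_rate=LoganParams(**raw["dev_rate"]),
                    mortality=MortalityParams(**raw["mortality"]),
                    dev_var=DevVarParams(**raw["dev_var"]),
                )
            )
        except (KeyError, TypeError) as e:
            raise ValueError(f"malformed record for stage {name!r}: {e}") from e
    al_raw = dict(d.get("adult_longevity") or {})
    family = al_raw.pop("family", None)
    if family == "stinner":
        al: AdultLongevity = StinnerParams(**al_raw)
    elif family == "hilbert_logan":
        al = HilbertLoganParams(**al_raw)
    else:
        raise ValueError(
            "adult_longevity.family must be 'stinner' or 'hilbert_logan'"
        )
    try:
        fec = FecundityParams(**d["fecundity"])
    except (KeyError, TypeError) as e:
        raise ValueError(f"malformed fecundity record: {e}") from e
    return SpeciesModel(
        species_name=str(d.get("species_name", "unnamed")),
        stages=stages,
        adult_longevity=al,
        fecundity=fec,
        sex_ratio=float(d.get("sex_ratio", 0.5)),
    )


def load_species(path) -> SpeciesModel:
    """Read a species parameter file (YAML) and validate it."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return species_from_dict(doc)


def save_species(sp: SpeciesModel, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(species_to_dict(sp), fh, sort_keys=False)
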