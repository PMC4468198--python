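"""Linking pest activity to maize yield loss per agro-climatic zone.

Maize production zones are altitude bands: lowland tropical (< 1000 m),
dry mid altitude (1000-1300 m), moist transitional (1300-1600 m) and
highland tropics (> 1600 m).  For each zone the mean activity index is
extracted from the interpolated AI raster, and observed zone-level
losses are regressed on it with ordinary least squares,

    Y = beta0 + beta1 * A,

where Y is percent maize yield loss and A the activity index.  The same
fitted line, fed future activity indices, projects future losses; the
difference Future - Current is the climate-driven change in loss.

With the default four zones the fit has a single residual degree of
freedom, so the reported inference statistics are fragile: a low-n
warning is always logged.  Predictions are raw linear values, never
clamped to [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mapping import Grid

__all__ = [
    "ZoneDefinition",
    "DEFAULT_ZONES",
    "YieldLossFit",
    "ZoneSummary",
    "zone_mean_index",
    "fit_loss_model",
    "predict_losses",
    "r_squared",
    "loss_change_table",
]

logger = logging.getLogger(__name__)

ZONE_NAMES = (
    "lowland tropical",
    "dry mid altitude",
    "moist transitional",
    "highland tropics",
)


@dataclass(frozen=True)
class ZoneDefinition:
    """An altitude band [alt_lo, alt_hi); the top band is closed above."""

    name: str
    alt_lo: float
    alt_hi: float

    def __post_init__(self):
        if self.name not in ZONE_NAMES:
            raise ValueError(f"zone name must be one of {ZONE_NAMES}")
        if not self.alt_hi > self.alt_lo:
            raise ValueError("alt_hi must exceed alt_lo")


#: the default agro-climatic bands, bottom to top of the gradient
DEFAULT_ZONES = (
    ZoneDefinition("lowland tropical", -np.inf, 1000.0),
    ZoneDefinition("dry mid altitude", 1000.0, 1300.0),
    ZoneDefinition("moist transitional", 1300.0, 1600.0),
    ZoneDefinition("highland tropics", 1600.0, np.inf),
)


@dataclass(frozen=True)
class YieldLossFit:
    """OLS fit of percent loss on activity index, with inference."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    df: int
    f_stat: float
    t_stat: float
    p_value: float
    r2: float


@dataclass(frozen=True)
class ZoneSummary:
    zone: ZoneDefinition
    mean_ai_current: float
    mean_ai_future: float
    loss_current: float
    loss_future: float

    @property
    def loss_change(self) -> float:
        return self.loss_future - self.loss_current


def zone_mean_index(ai: Grid, dem: Grid,
                    zones: Sequence[ZoneDefinition] = DEFAULT_ZONES) -> dict:
    """Mean AI over valid cells per altitude zone.

    A zone collects cells whose DEM elevation falls in [alt_lo, alt_hi)
    (the top zone is closed above by its infinite bound).  Zones with no
    cells map to None.
    """
    if not ai.same_geometry(dem):
        raise ValueError("AI and DEM geometries do not match")
    valid = ai.mask() & dem.mask()
    if not np.any(valid):
        raise ValueError("no valid cells in the AI/DEM overlay")
    elev = dem.values[valid]
    vals = ai.values[valid]
    out = {}
    for z in zones:
        sel = (elev >= z.alt_lo) & (elev < z.alt_hi)
        out[z.name] = float(vals[sel].mean()) if np.any(sel) else None
    return out


def fit_loss_model(observed: Sequence[float],
                   ai: Sequence[float]) -> YieldLossFit:
    """Ordinary least squares of observed percent loss on activity index."""
    y = np.asarray(observed, dtype=float)
    a = np.asarray(ai, dtype=float)
    if y.shape != a.shape or y.ndim != 1:
        raise ValueError("observed and ai must be equal-length 1-D sequences")
    if y.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.var(a) == 0.0:
        raise ValueError("degenerate fit: activity index has zero variance")
    if y.size <= 4:
        logger.warning(
            "fitting the loss model on only %d zones (df = %d); "
            "inference statistics are fragile", y.size, y.size - 2,
        )
    res = sm.OLS(y, sm.add_constant(a)).fit()
    return YieldLossFit(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        se_beta0=float(res.bse[0]),
        se_beta1=float(res.bse[1]),
        df=int(res.df_resid),
        f_stat=float(res.fvalue),
        t_stat=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        r2=float(res.rsquared),
    )


def predict_losses(fit: YieldLossFit, ai: Sequence[float]) -> np.ndarray:
    """beta0 + beta1 * AI per zone; raw linear predictions, not clamped.

    Negative predictions are biologically unattainable losses and are
    flagged in the log but reported as-is.
    """
    a = np.asarray(ai, dtype=float)
    pred = fit.beta0 + fit.beta1 * a
    neg = np.asarray(pred) < 0.0
    if np.any(neg):
        logger.warning("%d predicted loss(es) are negative; reported unclamped",
                       int(np.sum(neg)))
    return pred


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    if np.var(y) == 0.0 or np.var(p) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(y, p)[0, 1] ** 2)


def loss_change_table(summaries: Sequence[ZoneSummary]) -> pd.DataFrame:
    """Per-zone current/future/difference table with an Average row.

    The Average row holds the unweighted mean of each numeric column
    across the zones (so the average difference equals the difference of
    the column averages).
    """
    rows = [
        {
            "zone": s.zone.name,
            "current_pct": s.loss_current,
            "future_pct": s.loss_future,
            "change_pct": s.loss_change,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    avg = {
        "zone": "Average",
        "current_pct": df["current_pct"].mean(),
        "future_pct": df["future_pct"].mean(),
        "change_pct": df["change_pct"].mean(),
    }
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
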