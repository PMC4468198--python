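"""Reported transect yield-loss tables for East African stem borers.

Zone-level observed maize yield losses (from published field surveys)
and the reported loss-model coefficients and predicted losses for the
two altitudinal transects — Mount Kilimanjaro (Tanzania) and the Taita
Hills (Kenya) — for the two stem borer pests *Chilo partellus* and
*Busseola fusca*.  Zones run bottom-to-top of the gradient: lowland
tropical, dry mid altitude, moist transitional, highland tropics.

These small reference tables serve as desk-check inputs: inverting the
reported predictions through the reported coefficients recovers the
per-zone activity indices, from which the regression, the predictions
and the R-squared values can all be recomputed independently.
"""

from __future__ import annotations

ZONE_ORDER = (
    "lowland tropical",
    "dry mid altitude",
    "moist transitional",
    "highland tropics",
)

#: observed percent maize yield loss per zone (bottom to top), shared by
#: both transects of a species' loss model
OBSERVED_LOSS = {
    "chilo_partellus": (22.69, 11.09, 11.1, 0.01),
    "busseola_fusca": (0.48, 5.54, 14.60, 10.70),
}

#: reported OLS coefficients (beta0, beta1) and their standard errors,
#: plus reported fit statistics, per (species, transect)
LOSS_MODEL = {
    ("chilo_partellus", "kilimanjaro"): {
        "beta0": -20.893, "se_beta0": 8.051,
        "beta1": 3.087, "se_beta1": 0.753,
        "df": 1, "f_stat": 16.798, "t_stat": 4.099,
        "p_value": 0.055, "r2": 0.894,
    },
    ("chilo_partellus", "taita"): {
        "beta0": -27.961, "se_beta0": 10.998,
        "beta1": 3.844, "se_beta1": 1.059,
        "df": 1, "f_stat": 13.155, "t_stat": 3.627,
        "p_value": 0.068, "r2": 0.868,
    },
    ("busseola_fusca", "kilimanjaro"): {
        "beta0": -39.554, "se_beta0": 16.468,
        "beta1": 6.855, "se_beta1": 2.370,
        "df": 1, "f_stat": 8.364, "t_stat": 2.892,
        "p_value": 0.102, "r2": 0.807,
    },
    ("busseola_fusca", "taita"): {
        "beta0": -71.386, "se_beta0": 27.876,
        "beta1": 12.272, "se_beta1": 4.311,
        "df": 1, "f_stat": 8.104, "t_stat": 2.847,
        "p_value": 0.104, "r2": 0.802,
    },
}

#: reported predicted percent loss per zone (bottom to top):
#: (current 2013, future 2055) per (species, transect)
PREDICTED_LOSS = {
    ("chilo_partellus", "kilimanjaro"): {
        "current": (23.06, 12.14, 6.86, 2.84),
        "future": (28.10, 17.85, 12.41, 8.34),
    },
    ("chilo_partellus", "taita"): {
        "current": (21.42, 14.66, 7.04, 1.74),
        "future": (28.11, 21.19, 13.26, 7.74),
    },
    ("busseola_fusca", "kilimanjaro"): {
        "current": (1.17, 5.69, 10.97, 13.51),
        "future": (9.46, 12.27, 15.77, 14.88),
    },
    ("busseola_fusca", "taita"): {
        "current": (0.53, 6.91, 10.77, 13.40),
        "future": (13.78, 20.65, 31.67, 36.85),
    },
}

#: reported four-zone average loss change (future - current), percent
AVERAGE_LOSS_CHANGE = {
    ("chilo_partellus", "kilimanjaro"): 5.45,
    ("chilo_partellus", "taita"): 6.36,
    ("busseola_fusca", "kilimanjaro"): 5.26,
    ("busseola_fusca", "taita"): 17.84,
}


def invert_activity_index(species: str, transect: str,
                          scenario: str = "current") -> tuple:
    """Per-zone activity indices implied by the reported predictions.

    Inverts Y = beta0 + beta1*A through the reported coefficients:
    A = (Y - beta0) / beta1.  These recovered indices make the reported
    predictions the model's fitted values by construction.
    """
    coef = LOSS_MODEL[(species, transect)]
    pred = PREDICTED_LOSS[(species, transect)][scenario]
    return tuple((y - coef["beta0"]) / coef["beta1"] for y in pred)
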