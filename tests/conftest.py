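import numpy as np
import pytest

import phenorisk as pr


def deterministic_species(rate_per_day=0.1, fecundity=100.0, mortality_exp=-50.0,
                          beta=1e12, sex_ratio=0.5, t_base=8.0, t_max=42.0):
    """A species with flat development rate, ~no mortality and ~no variability.

    Inside (t_base, t_max) the Logan bracket is rescaled so the rate equals
    ``rate_per_day`` at 25 degC; mortality_exp=-50 makes stage mortality
    exp(-50) ~ 0; beta=1e6 collapses the multiplier distribution onto 1.
    """
    rho, delta = 0.15, 5.0
    bracket = np.exp(rho * (25.0 - t_base)) - np.exp(
        rho * (t_max - t_base) - (t_max - 25.0) / delta)
    logan = pr.LoganParams(psi=rate_per_day / bracket, rho=rho,
                           t_base=t_base, t_max=t_max, delta=delta)
    mort = pr.MortalityParams(mortality_exp, 0.0, 0.0)
    var = pr.DevVarParams("logit", beta)
    stages = [pr.StageModel(n, logan, mort, var) for n in ("egg", "larva", "pupa")]
    return pr.SpeciesModel(
        "deterministic", stages,
        pr.StinnerParams(c_max=20.0, k1=-5.0, k2=0.16),
        pr.FecundityParams(fecundity, 0.0, 0.0, 2.0, 0.15),
        sex_ratio,
    )


@pytest.fixture(scope="session")
def toy_species():
    return deterministic_species()


@pytest.fixture(scope="session")
def lowland_host():
    return pr.make_species("lowland_host")


@pytest.fixture(scope="session")
def highland_host():
    return pr.make_species("highland_host")


@pytest.fixture(scope="session")
def all_profiles():
    return {name: pr.make_species(name) for name in
            ("lowland_host", "highland_host",
             "lowland_parasitoid", "highland_parasitoid")}


@pytest.fixture(scope="session")
def demo_transect():
    return pr.make_transect(pr.TransectSpec(seed=1))


@pytest.fixture
def small_cfg():
    return pr.CohortConfig(n_individuals=200, seed=11)
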