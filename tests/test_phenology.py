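import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenorisk as pr

LOGAN = pr.LoganParams(psi=0.03, rho=0.15, t_base=10.0, t_max=40.0, delta=5.0)
MORT = pr.MortalityParams(-8.0, 0.45, -0.0105)
FEC = pr.FecundityParams(-300.0, 40.0, -0.8, 2.0, 0.15)


class TestDevelopmentRate:
    @pytest.mark.parametrize("t, expected", [
        (40.0, 0.0),            # exponentials cancel at the lethal maximum
        (45.0, 0.0),            # clamped beyond it
        (10.0, 0.0),            # zero at and below the base temperature
        (5.0, 0.0),
        (25.0, 0.1501814029806),  # direct evaluation of the closed form
    ])
    def test_closed_form(self, t, expected):
        assert pr.development_rate(t, LOGAN) == pytest.approx(expected, abs=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            pr.development_rate(float("nan"), LOGAN)

    @given(st.floats(min_value=-20.0, max_value=60.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_finite_non_negative(self, t):
        r = pr.development_rate(t, LOGAN)
        assert np.isfinite(r) and r >= 0.0

    def test_unimodal_for_shipped_species(self, all_profiles):
        # a single sign change of the discrete derivative on a 0.1 degC grid
        for sp in all_profiles.values():
            for stage in sp.stages:
                p = stage.dev_rate
                t = np.arange(p.t_base + 0.1, p.t_max, 0.1)
                r = pr.development_rate(t, p)
                sign = np.sign(np.diff(r))
                changes = np.count_nonzero(np.diff(sign[sign != 0]))
                assert changes <= 1


class TestStageMortality:
    def test_direct_evaluation(self):
        assert pr.stage_mortality(20.0, MORT) == pytest.approx(
            math.exp(-3.2), rel=1e-12)

    def test_clamped_at_one(self):
        p = pr.MortalityParams(1.0, 0.0, 0.0)  # exponent >= 0 everywhere
        assert pr.stage_mortality(30.0, p) == 1.0

    def test_vertex_is_extremum(self):
        t_star = -MORT.b1 / (2 * MORT.b2)
        m_star = pr.stage_mortality(t_star, MORT)
        for dt in (-2.0, -0.5, 0.5, 2.0):
            # b2 < 0: the exponent peaks at the vertex
            assert pr.stage_mortality(t_star + dt, MORT) <= m_star

    @given(st.floats(min_value=-20.0, max_value=60.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_fraction(self, t):
        m = pr.stage_mortality(t, MORT)
        assert 0.0 <= m <= 1.0


class TestDevMultiplier:
    def test_logit_median_is_one(self):
        p = pr.DevVarParams("logit", 3.7)
        assert pr.sample_dev_multiplier(0.5, p) == pytest.approx(1.0, abs=1e-14)

    def test_logit_upper_quartile(self):
        p = pr.DevVarParams("logit", 8.0)
        assert pr.sample_dev_multiplier(0.75, p) == pytest.approx(
            math.exp(math.log(3.0) / 8.0), rel=1e-12)

    def test_cloglog_anchor(self):
        p = pr.DevVarParams("cloglog", 8.0)
        u = 1.0 - math.exp(-1.0)
        assert pr.sample_dev_multiplier(u, p) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_bad_quantile(self, u):
        with pytest.raises(ValueError):
            pr.sample_dev_multiplier(u, pr.DevVarParams("logit", 8.0))

    @pytest.mark.parametrize("family", ["logit", "cloglog"])
    def test_quantile_strictly_increasing(self, family):
        p = pr.DevVarParams(family, 6.0)
        u = np.linspace(0.001, 0.999, 500)
        m = pr.sample_dev_multiplier(u, p)
        assert np.all(np.diff(m) > 0.0)

    def test_empirical_logit_median_near_one(self):
        rng = np.random.default_rng(42)
        draws = pr.sample_dev_multiplier(
            rng.uniform(1e-9, 1 - 1e-9, 100_000), pr.DevVarParams("logit", 8.0))
        assert abs(np.median(draws) - 1.0) < 0.01


class TestAdultCurves:
    def test_stinner_value(self):
        p = pr.StinnerParams(40.0, -6.0, 0.28)
        assert pr.adult_longevity(20.0, p) == pytest.approx(
            40.0 / (1.0 + math.exp(-0.4)), rel=1e-12)

    def test_stinner_flat_when_slope_zero(self):
        p = pr.StinnerParams(40.0, -1.0, 0.0)
        vals = [pr.adult_longevity(t, p) for t in (0.0, 15.0, 35.0)]
        assert vals[0] == vals[1] == vals[2]

    def test_stinner_vanishes_when_hot(self):
        p = pr.StinnerParams(40.0, -6.0, 0.28)
        assert pr.adult_longevity(500.0, p) < 1e-10

    def test_senescence_value(self):
        p = pr.HilbertLoganParams(0.1, 8.0, 10.0, 40.0, 6.0)
        expected = 0.1 * (400.0 / 464.0 - math.exp(-10.0 / 6.0))
        assert pr.senescence_rate(30.0, p) == pytest.approx(expected, rel=1e-12)

    def test_senescence_clamped_at_cold_and_lethal(self):
        p = pr.HilbertLoganParams(0.1, 8.0, 10.0, 40.0, 6.0)
        assert pr.senescence_rate(10.0, p) == 0.0   # bracket negative at base
        assert pr.senescence_rate(40.0, p) == 0.0   # t' ratio < 1 at t_max


class TestFecundity:
    def test_quadratic_value(self):
        assert pr.total_fecundity(25.0, FEC) == pytest.approx(200.0, abs=1e-10)

    def test_clamped_outside_roots(self):
        assert pr.total_fecundity(60.0, FEC) == 0.0

    def test_constant_when_linear_terms_zero(self):
        p = pr.FecundityParams(55.0, 0.0, 0.0, 2.0, 0.15)
        assert pr.total_fecundity(5.0, p) == 55.0

    def test_oviposition_whole_life(self):
        assert pr.oviposition_fraction(0.0, 1.0, FEC) == pytest.approx(1.0, abs=1e-12)

    def test_oviposition_additive(self):
        a = pr.oviposition_fraction(0.0, 0.5, FEC)
        b = pr.oviposition_fraction(0.5, 1.0, FEC)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_oviposition_closed_form(self):
        # integer-shape gamma CDF: P(x) = 1 - e^(-x/s)(1 + x/s), s = 0.15:
        # P(0.3)/P(1) = 0.593994.../0.990243... = 0.599847
        assert pr.oviposition_fraction(0.0, 0.3, FEC) == pytest.approx(
            0.5998467707, rel=1e-9)

    def test_oviposition_partition_sums_to_one(self):
        edges = np.linspace(0.0, 1.0, 14)
        total = sum(pr.oviposition_fraction(a, b, FEC)
                    for a, b in zip(edges[:-1], edges[1:]))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_oviposition_rejects_bad_interval(self):
        with pytest.raises(ValueError):
            pr.oviposition_fraction(0.5, 0.5, FEC)


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(psi=-0.1, rho=0.15, t_base=10, t_max=40, delta=5),
        dict(psi=0.1, rho=0.15, t_base=40, t_max=10, delta=5),
        dict(psi=0.1, rho=0.15, t_base=10, t_max=40, delta=-1),
    ])
    def test_logan_invariants(self, kwargs):
        with pytest.raises(ValueError):
            pr.LoganParams(**kwargs)

    def test_devvar_invariants(self):
        with pytest.raises(ValueError):
            pr.DevVarParams("probit", 8.0)
        with pytest.raises(ValueError):
            pr.DevVarParams("logit", -1.0)

    def test_species_stage_order_enforced(self, toy_species):
        stages = list(toy_species.stages)[::-1]
        with pytest.raises(ValueError):
            pr.SpeciesModel("x", stages, toy_species.adult_longevity,
                            toy_species.fecundity)

    def test_species_file_roundtrip(self, tmp_path, lowland_host):
        path = tmp_path / "sp.yaml"
        pr.save_species(lowland_host, path)
        back = pr.load_species(path)
        assert back == lowland_host

    def test_schema_rejects_missing_stage(self, lowland_host):
        doc = pr.species_to_dict(lowland_host)
        del doc["stages"]["larva"]
        with pytest.raises(ValueError, match="larva"):
            pr.species_from_dict(doc)
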