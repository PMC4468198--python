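import numpy as np
import pytest

import phenorisk as pr
from phenorisk.mapping import StationSample, _tps_kernel

TRANSECT_STATIONS = [
    # staggered 6-station layout on a synthetic slope (x, y in metres)
    (1250.0, 4750.0, 712.0),
    (5250.0, 6250.0, 921.0),
    (9250.0, 8750.0, 1143.0),
    (12750.0, 10250.0, 1351.0),
    (16250.0, 12750.0, 1568.0),
    (20250.0, 15250.0, 1803.0),
]


def transect_samples(values):
    return [StationSample(x, y, e, v)
            for (x, y, e), v in zip(TRANSECT_STATIONS, values)]


def small_dem():
    vals = np.linspace(600.0, 1900.0, 12 * 10).reshape(10, 12)
    return pr.Grid(12, 10, 0.0, 0.0, 500.0, -9999.0, vals)


class TestFitTps:
    def test_constant_field(self):
        s = transect_samples([4.2] * 6)
        m = pr.fit_tps(s)
        assert m.a0 == pytest.approx(4.2, abs=1e-8)
        assert np.allclose([m.ax, m.ay, m.az], 0.0, atol=1e-10)
        assert np.allclose(m.weights, 0.0, atol=1e-10)
        assert m.predict(3333.0, 777.0, 1234.0) == pytest.approx(4.2, abs=1e-8)

    def test_affine_field_absorbed_by_trend(self):
        vals = [1.0 + 2e-4 * x + 3e-4 * y + 1e-3 * e
                for x, y, e in TRANSECT_STATIONS]
        m = pr.fit_tps(transect_samples(vals))
        assert np.allclose(m.weights, 0.0, atol=1e-8)
        assert m.ax == pytest.approx(2e-4, rel=1e-6)
        assert m.az == pytest.approx(1e-3, rel=1e-6)

    def test_exact_interpolation_and_loo(self):
        rng = np.random.default_rng(8)
        vals = 5.0 + rng.normal(0.0, 1.0, 6)
        samples = transect_samples(vals)
        m = pr.fit_tps(samples, smoothing=0.0)
        for s in samples:
            assert abs(m.predict(s.x, s.y, s.elev) - s.value) < 1e-8
        # leave-one-out refit oracle: errors are finite and reported
        loo = []
        for i, s in enumerate(samples):
            rest = samples[:i] + samples[i + 1:]
            if len(rest) >= 4:
                mi = pr.fit_tps(rest)
                loo.append(mi.predict(s.x, s.y, s.elev) - s.value)
        assert np.all(np.isfinite(loo))

    def test_side_conditions(self):
        rng = np.random.default_rng(1)
        m = pr.fit_tps(transect_samples(5 + rng.normal(size=6)))
        x = m.station_xy[:, 0]
        y = m.station_xy[:, 1]
        scale = np.abs(m.weights).max() + 1e-30
        assert abs(m.weights.sum()) < 1e-8
        assert abs((m.weights * x).sum()) / (scale * np.abs(x).max()) < 1e-8
        assert abs((m.weights * y).sum()) / (scale * np.abs(y).max()) < 1e-8

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        vals = 5 + rng.normal(size=6)
        m1 = pr.fit_tps(transect_samples(vals))
        shifted = [StationSample(s.x + 1e4, s.y - 5e3, s.elev, s.value)
                   for s in transect_samples(vals)]
        m2 = pr.fit_tps(shifted)
        q = (4321.0, 9876.0, 1200.0)
        assert m1.predict(*q) == pytest.approx(
            m2.predict(q[0] + 1e4, q[1] - 5e3, q[2]), abs=1e-8)

    def test_kernel_value_at_zero(self):
        assert _tps_kernel(np.array([0.0]))[0] == 0.0

    def test_too_few_and_degenerate_layouts(self):
        with pytest.raises(ValueError, match="4 stations"):
            pr.fit_tps(transect_samples([1, 2, 3, 4, 5, 6])[:3])
        dup = transect_samples([1, 2, 3, 4, 5, 6])
        dup[1] = StationSample(dup[0].x, dup[0].y, 900.0, 2.0)
        with pytest.raises(ValueError, match="duplicate"):
            pr.fit_tps(dup)
        flat = [StationSample(x, 100.0, 3.0 * x, v) for x, v in
                zip((0.0, 1e3, 2e3, 3e3, 4e3, 5e3), (1, 2, 3, 4, 5, 6))]
        with pytest.raises(ValueError, match="collinear"):
            pr.fit_tps(flat)


class TestPredictGrid:
    def test_constant_model_constant_grid(self):
        m = pr.fit_tps(transect_samples([7.5] * 6))
        out = pr.predict_grid(m, small_dem())
        assert np.allclose(out.values, 7.5, atol=1e-7)

    def test_nodata_propagates(self):
        dem = small_dem()
        dem.values[3, 4] = dem.nodata
        m = pr.fit_tps(transect_samples([7.5] * 6))
        out = pr.predict_grid(m, dem)
        assert out.values[3, 4] == dem.nodata

    def test_station_at_cell_centre_reproduced(self):
        # put a station exactly on a DEM cell centre with the DEM's elevation
        dem = small_dem()
        gx, gy = dem.cell_centers()
        r, c = 4, 6
        st = [(gx[r, c], gy[r, c], dem.values[r, c])] + [
            (x, y, e) for x, y, e in TRANSECT_STATIONS[:5]]
        vals = [3.3, 1.0, 2.0, 1.5, 2.5, 2.2]
        samples = [StationSample(x, y, e, v) for (x, y, e), v in zip(st, vals)]
        out = pr.predict_grid(pr.fit_tps(samples), dem)
        assert out.values[r, c] == pytest.approx(3.3, abs=1e-6)


class TestGridAlgebra:
    def test_difference_and_antisymmetry(self):
        g = small_dem()
        h = g.copy_with(g.values + 0.05)
        d = pr.grid_difference(h, g)
        assert np.allclose(d.values[d.mask()], 0.05)
        swap = pr.grid_difference(g, h)
        assert np.allclose(d.values[d.mask()], -swap.values[swap.mask()])
        assert np.allclose(pr.grid_difference(g, g).values, 0.0)

    def test_difference_nodata_and_geometry(self):
        g = small_dem()
        h = g.copy_with(g.values.copy())
        h.values[0, 0] = h.nodata
        d = pr.grid_difference(h, g)
        assert d.values[0, 0] == d.nodata
        other = pr.Grid(3, 3, 0, 0, 1.0, -9999.0, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            pr.grid_difference(g, other)

    def test_sample_points(self):
        g = pr.Grid(3, 2, 0.0, 0.0, 10.0, -9999.0,
                    np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        # cell centres: bottom row y=5 -> values 4,5,6; top row y=15 -> 1,2,3
        assert pr.sample_points(g, [(5.0, 5.0)]) == [4.0]
        assert pr.sample_points(g, [(15.0, 15.0)]) == [2.0]
        assert pr.sample_points(g, [(-1.0, 5.0)]) == [None]
        assert pr.sample_points(g, [(35.0, 5.0)]) == [None]
        # corner point: round-half-up picks the east/north cell
        assert pr.sample_points(g, [(10.0, 10.0)]) == [2.0]


class TestAltitudeProfile:
    def test_constant_change(self):
        dem = small_dem()
        change = dem.copy_with(np.full(dem.values.shape, 0.7))
        prof = pr.altitude_profile(change, dem, 5)
        assert np.allclose(prof["mean_change"].dropna(), 0.7)

    def test_identity_change_equals_midpoints(self):
        dem = small_dem()
        prof = pr.altitude_profile(dem, dem, 8)
        width = (1900.0 - 600.0) / 8
        ok = prof.dropna()
        assert np.all(np.abs(ok["mean_change"] - ok["bin_mid_alt_m"]) <= width / 2)

    def test_single_bin_overall_mean(self):
        dem = small_dem()
        change = dem.copy_with(np.arange(120.0).reshape(10, 12))
        prof = pr.altitude_profile(change, dem, 1)
        assert prof["mean_change"].iloc[0] == pytest.approx(np.mean(change.values))

    def test_all_nodata_rejected(self):
        dem = small_dem()
        change = dem.copy_with(np.full(dem.values.shape, dem.nodata))
        with pytest.raises(ValueError):
            pr.altitude_profile(change, dem, 4)


class TestAsciiGrid:
    def test_roundtrip_lossless(self, tmp_path):
        rng = np.random.default_rng(4)
        vals = np.round(rng.uniform(0, 20, (5, 7)), 4)
        vals[2, 3] = -9999.0
        g = pr.Grid(7, 5, 1000.0, 2000.0, 250.0, -9999.0, vals)
        path = tmp_path / "g.asc"
        pr.write_ascii_grid(g, path)
        back = pr.read_ascii_grid(path)
        assert back.same_geometry(g)
        assert np.array_equal(back.values, g.values)
        # a second write-read cycle is bit-stable
        pr.write_ascii_grid(back, path)
        again = pr.read_ascii_grid(path)
        assert np.array_equal(again.values, back.values)

    def test_case_insensitive_read(self, tmp_path):
        path = tmp_path / "g.asc"
        path.write_text(
            "NCOLS 2\nNROWS 2\nXLLCORNER 0\nYLLCORNER 0\nCELLSIZE 1\n"
            "NODATA_VALUE -9\n1 2\n3 4\n")
        g = pr.read_ascii_grid(path)
        assert g.ncols == 2 and g.values[1, 1] == 4.0

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text("ncols 2\nnrows 2\n1 2\n3 4\n")
        with pytest.raises(ValueError, match="missing header"):
            pr.read_ascii_grid(path)
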