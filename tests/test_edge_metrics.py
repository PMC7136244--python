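"""Leading-edge percentile metric, expansion, attribution, bloom matchup."""

import numpy as np
import pandas as pd
import pytest

from bioadvect.edge_metrics import (LeadingEdgeSeries, UndefinedAttributionError,
                                    attribute_drivers, bloom_area_km2,
                                    bloom_matchup_fraction, edge_expansion,
                                    leading_edge, pic_leading_edge,
                                    trajectory_distance_km)
from bioadvect.geofields import FieldSeries, GeoGrid, degree_arc_km, haversine_km
from bioadvect.lagrangian import ACTIVE, BEACHED, ParticleEnsemble, TrajectorySet

REF = (30.0, 62.0)


def ensemble(lon, lat, status=None):
    n = len(lon)
    status = np.full(n, ACTIVE) if status is None else np.asarray(status)
    return ParticleEnsemble(ids=np.arange(n), lon=np.array(lon, float),
                            lat=np.array(lat, float),
                            time=np.datetime64("2000-09-01"), status=status)


def brute_percentile(values, pct):
    """Sorted linear-interpolation percentile, written out longhand."""
    v = np.sort(np.asarray(values, float))
    h = (len(v) - 1) * pct / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestLeadingEdge:
    def test_degenerate_single_point(self):
        e = leading_edge(ensemble([45.0] * 5, [70.0] * 5), REF)
        assert e.lon == 45.0 and e.lat == 70.0
        assert e.distance_km == pytest.approx(haversine_km(*REF, 45.0, 70.0))

    def test_twenty_particle_worked_example(self):
        lons = np.arange(41.0, 61.0)  # 41..60 E
        e = leading_edge(ensemble(lons, np.full(20, 70.0)), REF)
        assert e.lon == pytest.approx(59.05, abs=1e-9)
        assert e.lon == pytest.approx(brute_percentile(lons, 95), abs=1e-12)

    def test_permutation_invariance(self, rng):
        lons = rng.uniform(41, 60, 50)
        lats = rng.uniform(65, 75, 50)
        e1 = leading_edge(ensemble(lons, lats), REF)
        p = rng.permutation(50)
        e2 = leading_edge(ensemble(lons[p], lats[p]), REF)
        assert e1.lon == e2.lon and e1.lat == e2.lat

    def test_monotone_under_poleward_addition(self, rng):
        for _ in range(50):
            lons = rng.uniform(41, 55, 30)
            lats = rng.uniform(65, 72, 30)
            e1 = leading_edge(ensemble(lons, lats), REF)
            e2 = leading_edge(ensemble(np.append(lons, e1.lon + 1.0),
                                       np.append(lats, e1.lat + 1.0)), REF)
            assert e2.lon >= e1.lon and e2.lat >= e1.lat

    def test_pct_extremes_reduce_to_min_max(self):
        lons = np.array([42.0, 48.0, 55.0])
        lats = np.array([66.0, 70.0, 68.0])
        assert leading_edge(ensemble(lons, lats), REF, pct=100).lon == 55.0
        assert leading_edge(ensemble(lons, lats), REF, pct=0).lon == 42.0
        assert leading_edge(ensemble(lons, lats), REF, pct=0).lat == 66.0

    def test_empty_region_marks_missing_year(self):
        e = leading_edge(ensemble([35.0, 38.0], [65.0, 66.0]), REF, region_lon_min=40.0)
        assert e.missing

    def test_region_filter_applies(self):
        e = leading_edge(ensemble([35.0, 45.0, 50.0], [60.0, 70.0, 72.0]), REF)
        assert e.lon == pytest.approx(brute_percentile([45.0, 50.0], 95))


def pic_field(grid, pic_map):
    times = np.array(["2000-08-15"], dtype="datetime64[ns]")
    return FieldSeries(grid=grid, times=times, values=pic_map[None],
                       units="mol m-3", name="pic")


@pytest.fixture
def east_grid():
    lat = 69.0 + 0.25 * np.arange(10)
    lon = 39.0 + 0.25 * np.arange(12)
    return GeoGrid(lat_centers=lat, lon_centers=lon, spacing_deg=0.25)


class TestPicLeadingEdge:
    def test_single_bloom_pixel(self, east_grid):
        pic = np.zeros(east_grid.shape)
        pic[3, 8] = 0.01
        e = pic_leading_edge(pic_field(east_grid, pic), 0.001, REF)
        assert e.lon == east_grid.lon_centers[8]
        assert e.lat == east_grid.lat_centers[3]

    def test_uniform_band_percentile(self):
        # 100 evenly spaced latitude rows spanning 70..76N, all blooming
        lat = 70.0 + (6.0 / 99.0) * np.arange(100)
        grid = GeoGrid(lat_centers=lat, lon_centers=np.array([45.0, 45.0 + 6.0 / 99.0]),
                       spacing_deg=6.0 / 99.0)
        pic = np.full(grid.shape, 0.01)
        e = pic_leading_edge(pic_field(grid, pic), 0.001, REF)
        assert e.lat == pytest.approx(brute_percentile(np.repeat(lat, 2), 95), abs=1e-9)
        assert e.lat == pytest.approx(75.7, abs=0.05)

    def test_threshold_above_max_is_missing(self, east_grid):
        pic = np.full(east_grid.shape, 1e-5)
        e = pic_leading_edge(pic_field(east_grid, pic), 0.001, REF)
        assert e.missing


def edge_series(years, dist, source="EXP1"):
    years = np.asarray(years)
    return LeadingEdgeSeries(source=source, years=years,
                             edge_lon=np.full(years.size, 45.0),
                             edge_lat=np.full(years.size, 70.0),
                             edge_distance_km=np.asarray(dist, float))


class TestEdgeExpansion:
    def test_constant_edge_no_expansion(self):
        exp, tr = edge_expansion(edge_series(range(1998, 2008), [800.0] * 10))
        assert exp == pytest.approx(0.0, abs=1e-9)

    def test_linear_twenty_km_per_year_over_19_years(self):
        years = np.arange(1998, 2017)
        exp, tr = edge_expansion(edge_series(years, 500 + 20.0 * (years - 1998)))
        assert tr.slope == pytest.approx(20.0, abs=1e-9)
        assert exp == pytest.approx(360.0, abs=1e-6)  # 20 km/yr x 18 yr span

    def test_missing_year_handled_like_ols_oracle(self):
        years = np.arange(1998, 2008)
        dist = 500 + 15.0 * (years - 1998) + np.array([0, 1, -2, 0, 3, 0, -1, 2, 0, 1.0])
        dist[4] = np.nan
        exp, tr = edge_expansion(edge_series(years, dist))
        ok = np.isfinite(dist)
        t, y = years[ok].astype(float), dist[ok]
        slope = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
        assert tr.slope == pytest.approx(slope, abs=1e-10)
        assert exp == pytest.approx(slope * 9, abs=1e-8)

    def test_too_few_years_rejected(self):
        with pytest.raises(ValueError):
            edge_expansion(edge_series([1998, 1999], [1.0, 2.0]))


class TestAttribution:
    def test_single_driver_limit(self):
        years = np.arange(1998, 2008)
        e1 = edge_series(years, 500 + 10.0 * (years - 1998), "EXP1")
        e2 = edge_series(years, 500 + 10.0 * (years - 1998), "EXP2")
        e3 = edge_series(years, np.full(10, 500.0), "EXP3")
        res = attribute_drivers(e1, e2, e3)
        assert res.pct_currents == pytest.approx(100.0, abs=1e-6)
        assert res.pct_temperature == pytest.approx(0.0, abs=1e-6)

    def test_published_expansions_give_56_44_split(self):
        # expansions of 424 / 240 / 186 km over the same period
        years = np.arange(1998, 2017)
        span = (years - 1998).astype(float)
        e1 = edge_series(years, 424.0 / 18.0 * span, "EXP1")
        e2 = edge_series(years, 240.0 / 18.0 * span, "EXP2")
        e3 = edge_series(years, 186.0 / 18.0 * span, "EXP3")
        res = attribute_drivers(e1, e2, e3)
        assert res.pct_currents == pytest.approx(56.6, abs=0.05)
        assert res.pct_temperature == pytest.approx(43.9, abs=0.05)
        assert res.expansion_km["EXP1"] == pytest.approx(424.0, abs=1e-6)

    def test_scale_free(self, rng):
        years = np.arange(1998, 2008)
        base = 500 + 12.0 * (years - 1998) + rng.normal(0, 5, 10)
        e1 = edge_series(years, base, "EXP1")
        e2 = edge_series(years, 0.6 * base, "EXP2")
        e3 = edge_series(years, 0.4 * base, "EXP3")
        r1 = attribute_drivers(e1, e2, e3)
        e1s = edge_series(years, 3 * base, "EXP1")
        e2s = edge_series(years, 3 * 0.6 * base, "EXP2")
        e3s = edge_series(years, 3 * 0.4 * base, "EXP3")
        r2 = attribute_drivers(e1s, e2s, e3s)
        assert r1.pct_currents == pytest.approx(r2.pct_currents, rel=1e-12)
        assert r1.pct_temperature == pytest.approx(r2.pct_temperature, rel=1e-12)

    def test_overlap_clipping(self):
        e1 = edge_series(np.arange(1998, 2008), 10.0 * np.arange(10), "EXP1")
        e2 = edge_series(np.arange(2000, 2010), 6.0 * np.arange(10), "EXP2")
        e3 = edge_series(np.arange(1998, 2010), 4.0 * np.arange(12), "EXP3")
        res = attribute_drivers(e1, e2, e3)
        assert res.period == (2000, 2007)

    def test_zero_reference_expansion_rejected(self):
        years = np.arange(1998, 2008)
        flat = edge_series(years, np.full(10, 500.0), "EXP1")
        e2 = edge_series(years, 500 + 5.0 * (years - 1998), "EXP2")
        e3 = edge_series(years, 500 + 5.0 * (years - 1998), "EXP3")
        with pytest.raises(UndefinedAttributionError):
            attribute_drivers(flat, e2, e3)


class TestBloomMatchup:
    def test_particles_on_bloom_pixels(self, east_grid):
        pic = np.full(east_grid.shape, 0.01)
        fin = ensemble([40.0, 40.5], [70.0, 70.5])
        assert bloom_matchup_fraction(fin, pic_field(east_grid, pic), 0.001) == 1.0

    def test_particle_sixty_km_from_only_bloom(self, east_grid):
        pic = np.zeros(east_grid.shape)
        pic[0, 0] = 0.01  # pixel at (39.0E, 69.0N)
        blon, blat = 39.0, 69.0
        # walk due north ~60 km
        plat = blat + 60.0 / degree_arc_km(1.0, 0, "meridional")
        fin = ensemble([blon], [plat])
        assert haversine_km(blon, blat, blon, plat) == pytest.approx(60.0, abs=0.01)
        assert bloom_matchup_fraction(fin, pic_field(east_grid, pic), 0.001) == 0.0

    def test_three_in_one_out(self, east_grid):
        pic = np.zeros(east_grid.shape)
        pic[2, 2] = 0.01
        blon = east_grid.lon_centers[2]
        blat = east_grid.lat_centers[2]
        far_lat = blat + 80.0 / degree_arc_km(1.0, 0, "meridional")
        fin = ensemble([blon, blon + 0.1, blon, blon],
                       [blat, blat, blat + 0.2, far_lat])
        frac = bloom_matchup_fraction(fin, pic_field(east_grid, pic), 0.001)
        assert frac == pytest.approx(0.75)

    def test_beached_particles_excluded(self, east_grid):
        pic = np.full(east_grid.shape, 0.01)
        fin = ensemble([40.0, 40.5], [70.0, 70.5], status=[ACTIVE, BEACHED])
        assert bloom_matchup_fraction(fin, pic_field(east_grid, pic), 0.001) == 1.0

    def test_no_bloom_pixels_warns_and_returns_zero(self, east_grid):
        pic = np.zeros(east_grid.shape)
        fin = ensemble([40.0], [70.0])
        with pytest.warns(UserWarning):
            assert bloom_matchup_fraction(fin, pic_field(east_grid, pic), 0.001) == 0.0


def make_traj(lons, lats, start="2000-03-01"):
    snaps = []
    times = pd.date_range(start, periods=lons.shape[0], freq="D")
    n = lons.shape[1]
    for k, t in enumerate(times):
        snaps.append(ParticleEnsemble(ids=np.arange(n), lon=lons[k], lat=lats[k],
                                      time=t.to_datetime64(), status=np.full(n, ACTIVE)))
    return TrajectorySet(snapshots=snaps)


class TestTrajectoryDistance:
    def test_stationary_particles_travel_nothing(self):
        lons = np.full((5, 2), 45.0)
        lats = np.full((5, 2), 70.0)
        assert trajectory_distance_km(make_traj(lons, lats)) == 0.0

    def test_meridional_track_analytic_length(self):
        # 0.1 m/s due north for 100 days = 864.0 km
        days = 101
        step_deg = 0.1 * 86400.0 / (degree_arc_km(1.0, 0, "meridional") * 1000.0)
        lats = 60.0 + step_deg * np.arange(days)[:, None]
        lons = np.full((days, 1), 45.0)
        d = trajectory_distance_km(make_traj(lons, lats))
        assert d == pytest.approx(864.0, rel=1e-4)

    def test_cadence_invariance_for_straight_track(self):
        days = 101
        step = 0.05 * np.arange(days)
        lats = (60.0 + step)[:, None]
        lons = np.full((days, 1), 45.0)
        fine = trajectory_distance_km(make_traj(lons, lats))
        coarse = trajectory_distance_km(make_traj(lons[::2], lats[::2]))
        assert abs(fine - coarse) / fine < 1e-3

    def test_region_gate_on_final_position(self):
        lons = np.stack([np.full(2, 35.0), np.array([35.0, 45.0])])
        lats = np.full((2, 2), 70.0)
        d = trajectory_distance_km(make_traj(lons, lats))
        # only the particle finishing east of 40E counts
        assert d == pytest.approx(haversine_km(35.0, 70.0, 45.0, 70.0))

    def test_no_qualifying_particles_missing(self):
        lons = np.full((3, 2), 35.0)
        lats = np.full((3, 2), 70.0)
        assert np.isnan(trajectory_distance_km(make_traj(lons, lats)))


class TestBloomArea:
    def test_no_bloom_zero_area(self, east_grid):
        assert bloom_area_km2(pic_field(east_grid, np.zeros(east_grid.shape)), 0.001) == 0.0

    def test_single_quarter_degree_pixel_at_70N(self):
        lat = 69.875 + 0.25 * np.arange(3)  # middle row centred at 70.125
        grid = GeoGrid(lat_centers=np.array([69.75, 70.0, 70.25]),
                       lon_centers=np.array([45.0, 45.25, 45.5]), spacing_deg=0.25)
        pic = np.zeros(grid.shape)
        pic[1, 1] = 0.01  # the 70.0N cell
        area = bloom_area_km2(pic_field(grid, pic), 0.001)
        expected = degree_arc_km(0.25, 0, "meridional") * degree_arc_km(0.25, 70.0, "zonal")
        assert area == pytest.approx(expected, rel=1e-12)
        assert area == pytest.approx(264.3, abs=0.5)  # ~27.8 km x 9.5 km

    def test_additive_over_disjoint_pixel_sets(self, east_grid):
        a = np.zeros(east_grid.shape); a[1, 1] = 0.01
        b = np.zeros(east_grid.shape); b[5, 7] = 0.01
        both = a + b
        s = (bloom_area_km2(pic_field(east_grid, a), 0.001)
             + bloom_area_km2(pic_field(east_grid, b), 0.001))
        assert bloom_area_km2(pic_field(east_grid, both), 0.001) == pytest.approx(s, rel=1e-12)
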