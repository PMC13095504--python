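"""Trajectory integration oracles, geodesy, and biological filter semantics."""

import numpy as np
import pytest

from isodrift.raster import Raster
from isodrift.synth import defoliation_mask, make_wind_scenario
from isodrift.trajectory import (FlightParams, Release, Trajectory, Trap,
                                 apply_filters, batch_release, great_circle_km,
                                 simulate_trajectory)

T0 = np.datetime64("2020-07-21T21:00:00")


def flat_grid(nr=50, nc=50, cell_km=8.0, lat0=48.0, lon0=-66.0):
    dlat = cell_km / 110.574
    dlon = cell_km / (111.320 * np.cos(np.radians(lat0 - nr * dlat / 2)))
    return Raster(np.zeros((nr, nc)), lat0=lat0, lon0=lon0, dlat=dlat, dlon=dlon)


class TestGreatCircle:
    def test_zero_distance(self):
        assert great_circle_km(45.0, -60.0, 45.0, -60.0) == 0.0

    def test_one_degree_longitude_at_equator(self):
        assert great_circle_km(0.0, 0.0, 0.0, 1.0) == pytest.approx(111.195, abs=0.01)

    def test_arisaig_to_inverness(self):
        """The two Nova Scotia trap sites are 83.3 km apart (independent
        haversine oracle, frozen)."""
        d = great_circle_km(45.75, -62.16, 46.196, -61.294)
        assert 83.0 <= d <= 85.0
        assert d == pytest.approx(83.296, abs=0.01)

    def test_bad_latitude_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            great_circle_km(91.0, 0.0, 0.0, 0.0)


class TestIntegrator:
    def test_uniform_wind_matches_closed_form(self):
        """10 m/s east + 2.5 m/s airspeed for 1 h: 45.0 km due east."""
        grid = flat_grid()
        wind = make_wind_scenario("uniform", grid, T0, duration_h=10.0, u=10.0, v=0.0)
        rel = Release(lat=46.3, lon=-64.2, alt_m=300.0, time=T0)
        p = FlightParams(duration_h=1.0, dt=60.0)
        tr = simulate_trajectory(rel, wind, p)
        d = great_circle_km(rel.lat, rel.lon, tr.lats[-1], tr.lons[-1])
        assert d == pytest.approx(45.0, rel=5e-3)
        assert tr.lats[-1] == pytest.approx(rel.lat, abs=1e-9)
        assert tr.lons[-1] > rel.lon

    def test_nine_hour_endpoint_within_half_percent(self):
        grid = flat_grid(nr=80, nc=80)
        wind = make_wind_scenario("uniform", grid, T0, duration_h=10.0, u=0.0, v=-10.0)
        rel = Release(lat=47.5, lon=-63.5, alt_m=600.0, time=T0)
        tr = simulate_trajectory(rel, wind, FlightParams(duration_h=9.0, dt=60.0))
        d = great_circle_km(rel.lat, rel.lon, tr.lats[-1], tr.lons[-1])
        expect = (10.0 + 2.5) * 9 * 3.6  # km
        assert d == pytest.approx(expect, rel=5e-3)

    def test_dt_halving_changes_endpoint_below_point1_percent(self):
        grid = flat_grid(nr=80, nc=80)
        wind = make_wind_scenario("uniform", grid, T0, duration_h=10.0,
                                  u=-7.0, v=4.0)
        rel = Release(lat=46.8, lon=-62.8, alt_m=300.0, time=T0)
        a = simulate_trajectory(rel, wind, FlightParams(duration_h=9.0, dt=60.0))
        b = simulate_trajectory(rel, wind, FlightParams(duration_h=9.0, dt=30.0))
        sep = great_circle_km(a.lats[-1], a.lons[-1], b.lats[-1], b.lons[-1])
        path = (np.sum([great_circle_km(a.lats[i], a.lons[i], a.lats[i + 1], a.lons[i + 1])
                        for i in range(len(a) - 1)]))
        assert sep / path < 1e-3

    def test_zero_wind_means_no_displacement(self):
        grid = flat_grid()
        wind = make_wind_scenario("uniform", grid, T0, duration_h=3.0, u=0.0, v=0.0)
        rel = Release(lat=46.3, lon=-64.2, alt_m=300.0, time=T0)
        tr = simulate_trajectory(rel, wind, FlightParams(duration_h=2.0))
        assert np.all(tr.lats == rel.lat) and np.all(tr.lons == rel.lon)

    def test_rotating_flow_arc_length_oracle(self):
        """Solid-body vortex: tangential speed is ωr + airspeed, so the
        arc length over t is (ωr₀ + 2.5)·t within 1% (2-h window keeps the
        Euler radial drift negligible)."""
        grid = flat_grid(nr=80, nc=80)
        omega = 1.4e-4
        wind = make_wind_scenario("rotating", grid, T0, duration_h=4.0, omega=omega)
        lat_c = grid.lats.mean()
        lon_c = grid.lons.mean()
        # start 60 km east of the vortex center
        r0_km = 60.0
        lon_r = lon_c + r0_km / (111.320 * np.cos(np.radians(lat_c)))
        rel = Release(lat=float(lat_c), lon=float(lon_r), alt_m=300.0, time=T0)
        t_h = 2.0
        tr = simulate_trajectory(rel, wind, FlightParams(duration_h=t_h, dt=60.0))
        arc = np.sum([great_circle_km(tr.lats[i], tr.lons[i],
                                      tr.lats[i + 1], tr.lons[i + 1])
                      for i in range(len(tr) - 1)])
        expect = (omega * r0_km * 1000.0 + 2.5) * t_h * 3.6  # m/s × h → km
        assert arc == pytest.approx(expect, rel=0.01)

    def test_release_outside_wind_span_rejected(self):
        grid = flat_grid()
        wind = make_wind_scenario("uniform", grid, T0, duration_h=3.0)
        rel = Release(lat=46.3, lon=-64.2, alt_m=300.0,
                      time=T0 + np.timedelta64(5, "h"))
        with pytest.raises(ValueError, match="time span"):
            simulate_trajectory(rel, wind, FlightParams())

    def test_lapse_rate_cools_high_releases(self):
        grid = flat_grid()
        wind = make_wind_scenario("uniform", grid, T0, duration_h=3.0, temp=22.0)
        p = FlightParams(duration_h=1.0)
        low = simulate_trajectory(Release(46.3, -64.2, 300.0, T0), wind, p)
        high = simulate_trajectory(Release(46.3, -64.2, 900.0, T0), wind, p)
        assert np.allclose(low.temps, 22.0 - 6.5 * 0.3)
        assert np.allclose(high.temps, 22.0 - 6.5 * 0.9)


def _traj(times_s, lats, lons, alts, temps):
    t0 = np.datetime64("2020-07-21T21:00:00")
    return Trajectory(
        release=Release(lats[0], lons[0], alts[0], t0),
        times=t0 + np.asarray(times_s).astype("timedelta64[s]"),
        lats=np.asarray(lats, float), lons=np.asarray(lons, float),
        alts=np.asarray(alts, float), temps=np.asarray(temps, float))


class TestFilters:
    # a straight westward path passing directly over the trap at vertex 3
    TRAP = Trap("T", 46.0, -62.0)
    LONS = [-61.2, -61.4, -61.6, -62.0, -62.4, -62.6]
    LATS = [46.0] * 6
    TIMES = [0, 600, 1200, 1800, 2400, 3000]

    def _mk(self, temps, alts=None):
        alts = alts if alts is not None else [400.0] * 6
        return _traj(self.TIMES, self.LATS, self.LONS, alts, temps)

    def test_envelope_compliant_path_retained(self):
        tr = apply_filters(self._mk([18, 19, 20.4, 16, 15.5, 18]), [self.TRAP],
                           FlightParams())
        assert tr.verdict == "retained"
        assert tr.first_intersection[0] == "T"

    def test_cold_vertex_before_intersection_discards(self):
        tr = apply_filters(self._mk([18, 14.9, 18, 18, 18, 18]), [self.TRAP],
                           FlightParams())
        assert tr.verdict == "discarded_cold"

    def test_cold_only_after_intersection_is_retained(self):
        tr = apply_filters(self._mk([18, 18, 18, 18, 10, 5]), [self.TRAP],
                           FlightParams())
        assert tr.verdict == "retained"

    def test_low_altitude_before_intersection_discards(self):
        tr = apply_filters(self._mk([18] * 6, [400, 240, 400, 400, 400, 400]),
                           [self.TRAP], FlightParams())
        assert tr.verdict == "discarded_low"

    def test_cold_takes_precedence_over_low(self):
        tr = apply_filters(self._mk([18, 14, 18, 18, 18, 18],
                                    [400, 200, 400, 400, 400, 400]),
                           [self.TRAP], FlightParams())
        assert tr.verdict == "discarded_cold"

    def test_no_trap_crossing_is_no_intersection(self):
        far = Trap("far", 40.0, -70.0)
        tr = apply_filters(self._mk([18] * 6), [far], FlightParams())
        assert tr.verdict == "no_intersection"
        assert tr.first_intersection is None

    def test_segment_interpolation_catches_stepped_over_trap(self):
        """A two-vertex hop that jumps across the 10-km circle still
        intersects."""
        tr = _traj([0, 3600], [46.0, 46.0], [-61.0, -63.0],
                   [400, 400], [18, 18])
        out = apply_filters(tr, [self.TRAP], FlightParams())
        assert out.verdict == "retained"

    def test_filters_are_idempotent(self):
        tr = apply_filters(self._mk([18, 14, 18, 18, 18, 18]), [self.TRAP],
                           FlightParams())
        again = apply_filters(tr, [self.TRAP], FlightParams())
        assert again.verdict == tr.verdict
        assert again.first_intersection == tr.first_intersection


class TestBatchRelease:
    def test_counts_are_cells_times_times_times_alts(self):
        grid = flat_grid(nr=30, nc=30)
        wind = make_wind_scenario("uniform", grid, np.datetime64("2020-07-21T19:00:00"),
                                  duration_h=14.0, u=5.0, v=0.0)
        defol = defoliation_mask(grid.like(np.zeros(grid.shape)), [(15, 10)],
                                 half_size=0)
        defol2 = defoliation_mask(grid.like(np.zeros(grid.shape)),
                                  [(15, 10), (20, 12)], half_size=0)
        p = FlightParams(duration_h=2.0)
        assert len(batch_release(defol, wind, p, ["2020-07-21"])) == 9
        assert len(batch_release(defol2, wind, p, ["2020-07-21"])) == 18

    def test_empty_mask_rejected(self):
        grid = flat_grid(nr=30, nc=30)
        wind = make_wind_scenario("uniform", grid, T0, duration_h=3.0)
        empty = grid.like(np.zeros(grid.shape))
        with pytest.raises(ValueError, match="empty defoliation"):
            batch_release(empty, wind, FlightParams(), ["2020-07-21"])

    def test_masked_cells_never_release(self):
        grid = flat_grid(nr=30, nc=30)
        vals = np.zeros(grid.shape)
        vals[5, 5] = 1.0
        vals[6, 6] = np.nan   # nodata cell must not release
        defol = grid.like(vals)
        wind = make_wind_scenario("uniform", grid, np.datetime64("2020-07-21T19:00:00"),
                                  duration_h=14.0)
        trajs = batch_release(defol, wind, FlightParams(duration_h=1.0),
                              ["2020-07-21"])
        assert {t.release.cell for t in trajs} == {(5, 5)}


class TestScenarioOutcomes:
    def _run(self, scenario):
        grid = flat_grid(nr=40, nc=40)
        t0 = np.datetime64("2020-07-21T19:00:00")
        wind = make_wind_scenario(scenario, grid, t0, duration_h=14.0,
                                  source_rc=(20, 28), trap_rc=(20, 4))
        defol = defoliation_mask(grid.like(np.zeros(grid.shape)),
                                 [wind.meta["source_rc"]], half_size=1)
        trap_lat, trap_lon = wind.meta["trap_latlon"]
        trap = Trap("T1", trap_lat, trap_lon)
        p = FlightParams()
        trajs = [apply_filters(t, [trap], p)
                 for t in batch_release(defol, wind, p, ["2020-07-21"])]
        return trajs

    def test_channel_scenario_produces_retained_intersections(self):
        trajs = self._run("channel_to_trap")
        verdicts = [t.verdict for t in trajs]
        assert verdicts.count("retained") >= 1

    def test_cold_pocket_discards_some_of_the_same_releases(self):
        trajs = self._run("cold_pocket")
        verdicts = [t.verdict for t in trajs]
        assert verdicts.count("discarded_cold") >= 1

    def test_verdict_counts_conserve_releases(self):
        trajs = self._run("channel_to_trap")
        counts = {}
        for t in trajs:
            counts[t.verdict] = counts.get(t.verdict, 0) + 1
        assert sum(counts.values()) == len(trajs) == 81
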