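import numpy as np
import pytest

from physiosdm.coldstress import (
    OverwinterWindow,
    PopulationCTmin,
    StressResult,
    clip_window,
    count_stress,
    depth_average,
    drop_incomplete_stations,
    interpolate_to_grid,
    pool_ctmin,
)
from physiosdm.grids import GridDef

from .conftest import make_profile, make_station


def brute_force_stress(profile, ctmin):
    """Per-interval loop oracle for events and stress days."""
    events = 0
    days = set()
    for t, temp in zip(profile.timestamps, profile.temps):
        if temp < ctmin:
            events += 1
            days.add(str(t)[:10])
    return events, len(days)


class TestOverwinterWindow:
    def test_non_leap_spring_has_151_days(self):
        w = OverwinterWindow(2018)  # spring 2019, non-leap
        assert w.n_days == 151
        assert w.n_intervals == 1208

    def test_leap_spring_has_152_days(self):
        w = OverwinterWindow(2019)  # spring 2020, leap
        assert w.n_days == 152

    def test_single_year_policy_stays_within_one_calendar_year(self):
        w = OverwinterWindow(2020, "single_year")
        t = np.array(
            ["2020-11-01T00:00", "2020-02-15T00:00", "2021-02-15T00:00"],
            dtype="datetime64[s]",
        )
        assert list(w.contains(t)) == [True, True, False]


class TestClipWindow:
    def test_full_year_clips_to_window_intervals(self):
        n = 366 * 8  # cover Oct 2018 .. Oct 2019
        profile = make_profile(np.full(n, 5.0), start="2018-10-01T00:00")
        w = OverwinterWindow(2018)
        clipped = clip_window(profile, w)
        assert clipped.timestamps.size == 1208
        assert clipped.timestamps[0] == np.datetime64("2018-11-01T00:00", "s")
        assert clipped.timestamps[-1] == np.datetime64("2019-03-31T21:00", "s")

    def test_series_already_inside_window_unchanged(self):
        profile = make_profile(np.full(80, 5.0), start="2019-12-01T00:00")
        clipped = clip_window(profile, OverwinterWindow(2019))
        np.testing.assert_array_equal(clipped.timestamps, profile.timestamps)

    def test_no_overlap_is_error(self):
        profile = make_profile(np.full(8, 5.0), start="2019-06-01T00:00")
        with pytest.raises(ValueError, match="does not overlap"):
            clip_window(profile, OverwinterWindow(2019))


class TestDepthAverage:
    def test_mean_over_depths_in_range(self):
        st = make_station({10: [2.0], 40: [4.0]})
        assert depth_average(st, (10, 40)).temps[0] == pytest.approx(3.0)

    def test_single_depth_identity(self):
        st = make_station({20: [1.5, 2.5]})
        np.testing.assert_array_equal(depth_average(st, (10, 40)).temps, [1.5, 2.5])

    def test_depths_outside_range_excluded(self):
        st = make_station({5: [100.0], 10: [2.0], 30: [4.0], 50: [100.0]})
        assert depth_average(st, (10, 40)).temps[0] == pytest.approx(3.0)

    def test_missing_at_one_depth_makes_interval_missing(self):
        st = make_station({10: [2.0, np.nan], 40: [4.0, 4.0]})
        prof = depth_average(st, (10, 40))
        assert prof.temps[0] == 3.0 and np.isnan(prof.temps[1])

    def test_no_depth_in_range_is_error(self):
        st = make_station({5: [1.0]})
        with pytest.raises(ValueError, match="no depth"):
            depth_average(st, (10, 40))


class TestDropIncompleteStations:
    def _full_window_station(self, station_id, missing_at=None, seed=0):
        w = OverwinterWindow(2018)
        n = w.n_intervals
        temps = np.full(n, 5.0)
        if missing_at is not None:
            temps[missing_at] = np.nan
        return make_station(
            {10: temps, 40: temps.copy()}, start="2018-11-01T00:00",
            station_id=station_id,
        )

    def test_one_missing_interval_drops_station(self):
        st = self._full_window_station("S000", missing_at=100)
        assert drop_incomplete_stations([st], OverwinterWindow(2018)) == []

    def test_complete_station_kept(self):
        st = self._full_window_station("S000")
        assert len(drop_incomplete_stations([st], OverwinterWindow(2018))) == 1

    def test_matches_exhaustive_missing_scan(self):
        rng = np.random.default_rng(3)
        w = OverwinterWindow(2018)
        stations, expect = [], []
        for i in range(20):
            has_gap = rng.random() < 0.3
            st = self._full_window_station(
                f"S{i:03d}", missing_at=int(rng.integers(0, w.n_intervals)) if has_gap else None
            )
            stations.append(st)
            if not np.isnan(st.temps).any():
                expect.append(st.station_id)
        kept = drop_incomplete_stations(stations, w)
        assert [s.station_id for s in kept] == expect


class TestCountStress:
    def test_always_above_threshold_gives_zero(self):
        w = OverwinterWindow(2018)
        prof = make_profile(np.full(w.n_intervals, 5.0), start="2018-11-01T00:00")
        res = count_stress(prof, 0.85, w)
        assert (res.n_events, res.n_stress_days) == (0, 0)

    def test_always_below_threshold_saturates(self):
        w = OverwinterWindow(2018)
        prof = make_profile(np.full(w.n_intervals, -5.0), start="2018-11-01T00:00")
        res = count_stress(prof, 0.85, w)
        assert (res.n_events, res.n_stress_days) == (1208, 151)

    def test_single_dip_is_one_event_one_day(self):
        w = OverwinterWindow(2018)
        temps = np.full(w.n_intervals, 5.0)
        temps[500] = 0.85 - 0.1
        res = count_stress(make_profile(temps, start="2018-11-01T00:00"), 0.85, w)
        assert (res.n_events, res.n_stress_days) == (1, 1)

    def test_exactly_at_threshold_is_not_an_event(self):
        # "fell below" is strict: a profile sitting at CT_min never stresses
        w = OverwinterWindow(2018)
        prof = make_profile(np.full(w.n_intervals, 0.85), start="2018-11-01T00:00")
        res = count_stress(prof, 0.85, w)
        assert res.n_events == 0

    def test_sinusoid_matches_brute_force_loop(self):
        w = OverwinterWindow(2018)
        t = np.arange(w.n_intervals)
        temps = 2.0 + 3.0 * np.sin(2 * np.pi * t / (8 * 30)) - 0.002 * t
        prof = make_profile(temps, start="2018-11-01T00:00")
        res = count_stress(prof, 0.85, w)
        events, days = brute_force_stress(prof, 0.85)
        assert (res.n_events, res.n_stress_days) == (events, days)

    def test_random_series_match_oracle_and_monotone_in_ctmin(self):
        w = OverwinterWindow(2018)
        rng = np.random.default_rng(21)
        for _ in range(10):
            temps = rng.normal(loc=rng.uniform(-2, 2), scale=2.0, size=w.n_intervals)
            prof = make_profile(temps, start="2018-11-01T00:00")
            prev_days = -1
            for ctmin in (-3.0, -1.0, 0.0, 0.85, 2.0, 4.0):
                res = count_stress(prof, ctmin, w)
                events, days = brute_force_stress(prof, ctmin)
                assert (res.n_events, res.n_stress_days) == (events, days)
                assert 0 <= res.n_stress_days <= w.n_days
                assert res.n_events >= res.n_stress_days
                assert res.n_stress_days >= prev_days  # monotone in CT_min
                prev_days = res.n_stress_days

    def test_missing_values_are_an_error(self):
        w = OverwinterWindow(2018)
        temps = np.full(w.n_intervals, 5.0)
        temps[10] = np.nan
        with pytest.raises(ValueError, match="missing"):
            count_stress(make_profile(temps, start="2018-11-01T00:00"), 0.85, w)


class TestInterpolateToGrid:
    def _result(self, lon, lat, days, station_id="S000"):
        w = OverwinterWindow(2018)
        return StressResult(
            station_id=station_id, lon=lon, lat=lat,
            n_events=days, n_stress_days=days, window=w, ctmin_used=0.85,
        )

    def test_single_station_gives_constant_raster(self, small_grid):
        rast = interpolate_to_grid([self._result(85.5, 31.5, 42)], small_grid)
        assert np.all(rast.values == 42.0)

    def test_cell_at_station_reproduces_station_value(self, small_grid):
        lon, lat = small_grid.cell_center(2, 3)
        results = [
            self._result(float(lon), float(lat), 10, "S000"),
            self._result(85.95, 31.05, 50, "S001"),
        ]
        rast = interpolate_to_grid(results, small_grid)
        assert rast.values[2, 3] == 10.0

    def test_midpoint_of_two_stations_is_their_mean(self):
        grid = GridDef(west_lon=0.0, north_lat=1.0, n_rows=1, n_cols=3, cell_size=1.0)
        # station at centre of cols 0 and 2; the middle cell is equidistant
        results = [
            self._result(0.5, 0.5, 10, "S000"),
            self._result(2.5, 0.5, 30, "S001"),
        ]
        rast = interpolate_to_grid(results, grid, idw_power=2.0, k_neighbors=2)
        assert rast.values[0, 1] == pytest.approx(20.0)

    def test_values_bounded_by_station_range(self, small_grid):
        rng = np.random.default_rng(5)
        results = [
            self._result(rng.uniform(85, 86), rng.uniform(31, 32), int(d), f"S{i:03d}")
            for i, d in enumerate(rng.integers(0, 151, 8))
        ]
        rast = interpolate_to_grid(results, small_grid)
        vals = [r.n_stress_days for r in results]
        assert rast.values.min() >= min(vals) and rast.values.max() <= max(vals)

    def test_zero_stations_is_error(self, small_grid):
        with pytest.raises(ValueError, match="no stations"):
            interpolate_to_grid([], small_grid)


class TestPoolCTmin:
    def test_equal_n_populations_pool_to_simple_mean(self):
        pops = [
            PopulationCTmin("Gar", 12, 0.9, 0.5, 1.2, sd=0.2),
            PopulationCTmin("Zhongba", 12, 0.8, 0.6, 1.0, sd=0.1),
        ]
        summary = pool_ctmin(pops)
        assert summary.pooled_value == pytest.approx(0.85)
        assert summary.overall_range == pytest.approx(0.7)

    def test_weighting_by_sample_size(self):
        pops = [
            PopulationCTmin("a", 30, 1.0, 0.8, 1.2),
            PopulationCTmin("b", 10, 2.0, 1.5, 2.5),
        ]
        assert pool_ctmin(pops).pooled_value == pytest.approx(1.25)

    def test_single_population_is_identity(self):
        pops = [PopulationCTmin("only", 5, 1.1, 0.9, 1.4)]
        s = pool_ctmin(pops)
        assert s.pooled_value == 1.1 and s.overall_range == pytest.approx(0.5)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            PopulationCTmin("bad", 0, 1.0, 0.5, 1.5)
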