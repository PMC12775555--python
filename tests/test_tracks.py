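"""Track phenology: flight classification, visits, arrival and nest detection."""

import numpy as np
import pandas as pd
import pytest

from pinkfoot import synthetic as syn
from pinkfoot import tracks as tr
from pinkfoot.config import AnalysisConfig
from pinkfoot.geo import offset_point

from conftest import breeding_only_scenario


def _fix(ts, lat, lon, speed=np.nan, animal="a1"):
    return {"animal_id": animal, "timestamp": pd.Timestamp(ts), "lat": lat,
            "lon": lon, "ground_speed": speed}


def _track(rows):
    return pd.DataFrame(rows)


class TestFlying:
    def test_speed_threshold_boundary(self):
        assert not tr.is_flying(pd.Series(_fix("2022-05-01 10:00", 60, 10, 14.9)))
        assert tr.is_flying(pd.Series(_fix("2022-05-01 10:00", 60, 10, 15.0)))

    def test_derived_speed_from_displacement(self):
        prev = pd.Series(_fix("2022-05-01 10:00", 60.0, 10.0))
        # ~30 km north in one hour -> 30 km/h -> flying
        lat2, _ = offset_point(60.0, 10.0, 0.0, 30_000.0)
        cur = pd.Series(_fix("2022-05-01 11:00", float(lat2), 10.0))
        assert tr.is_flying(cur, prev)

    def test_no_speed_no_previous_raises(self):
        with pytest.raises(ValueError):
            tr.is_flying(pd.Series(_fix("2022-05-01 10:00", 60, 10)))


class TestVisits:
    def test_generator_truth_recovered(self, noiseless_scenario, acfg):
        fixes, truth = syn.gen_track(noiseless_scenario, "goose000", 2022)
        v = tr.visit_dates(fixes, tr.StopoverSite("trondelag", 63.5, 10.5), acfg)
        assert v.arrival_day == truth.site_arrival["trondelag"]
        assert v.departure_day == truth.site_departure["trondelag"]

    def test_flyover_yields_none(self, acfg):
        rows = [_fix(f"2022-05-01 {h:02d}:00", 63.5, 10.5 + 0.01 * h, speed=70.0)
                for h in range(10)]
        assert tr.visit_dates(_track(rows), tr.StopoverSite("s", 63.5, 10.5), acfg) is None

    def test_two_bouts_first_last_convention(self, acfg):
        rows = []
        for d in list(range(10, 16)) + list(range(25, 31)):
            rows.append(_fix(f"2022-01-{d:02d} 12:00", 63.5, 10.5, speed=2.0))
        for d in range(16, 25):  # between bouts: far away
            rows.append(_fix(f"2022-01-{d:02d} 12:00", 70.0, 30.5, speed=2.0))
        v = tr.visit_dates(_track(rows), tr.StopoverSite("s", 63.5, 10.5), acfg)
        assert (v.arrival_day, v.departure_day) == (10, 30)

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            tr.StopoverSite("s", 60, 10, radius_km=150)


class TestBreedingArrival:
    def test_exact_boundary_not_arrived(self, acfg):
        rows = [_fix("2022-06-01 10:00", 76.5640, 16.0, 2.0)]
        assert tr.breeding_arrival(_track(rows), "svalbard", acfg) is None

    def test_generator_truth(self, noiseless_scenario, acfg):
        fixes, truth = syn.gen_track(noiseless_scenario, "goose001", 2022)  # new route
        day = tr.breeding_arrival(fixes, "novaya_zemlya", acfg)
        assert day == truth.breeding_arrival_day

    def test_mainland_track_none(self, acfg):
        rows = [_fix(f"2022-06-{d:02d} 10:00", 63.0, 10.0, 2.0) for d in range(1, 8)]
        assert tr.breeding_arrival(_track(rows), "svalbard", acfg) is None
        with pytest.raises(ValueError):
            tr.breeding_arrival(_track(rows), "greenland", acfg)


class TestStationarity:
    def test_all_identical_point(self, acfg):
        rows = [_fix(f"2022-06-10 {h:02d}:00", 78.0, 16.0, 0.5) for h in range(10)]
        frac, (la, lo) = tr.daily_stationarity(_track(rows), 161, acfg)
        assert frac == 1.0 and la == 78.0 and lo == 16.0

    def test_fifty_fifty_split(self, acfg):
        rows = []
        for h in range(16):
            if h % 2 == 0:
                rows.append(_fix(f"2022-06-10 {h:02d}:00", 78.0, 16.0, 0.5))
            else:  # foraging ~2 km away, alternating so the still cluster is the nest
                la, lo = offset_point(78.0, 16.0, 2000.0 + 100 * h, 1500.0)
                rows.append(_fix(f"2022-06-10 {h:02d}:00", float(la), float(lo), 3.0))
        frac, _ = tr.daily_stationarity(_track(rows), 161, acfg)
        assert frac == 0.5

    def test_too_few_fixes_excluded(self, acfg):
        rows = [_fix("2022-06-10 10:00", 78.0, 16.0, 0.5)]
        assert tr.daily_stationarity(_track(rows), 161, acfg) is None


class TestNestDetection:
    def test_generator_nest_recovered(self, acfg):
        cfg = breeding_only_scenario(21, 1, propensity=1.1, attendance=0.95,
                                     fixed_nest_days=30)
        fixes, truth = syn.gen_track(cfg, "g000", 2022)
        nest = tr.detect_nest(fixes, acfg)
        assert nest is not None
        assert abs(nest.laying_day - truth.laying_day) <= 1
        assert nest.success and abs(nest.hatch_day - truth.hatch_day) <= 1
        # nest coordinate within tens of metres of truth
        from pinkfoot.geo import haversine_km
        assert haversine_km(nest.lat, nest.lon, truth.nest_lat, truth.nest_lon) < 0.05

    @pytest.mark.parametrize("nest_days,expect_nest,expect_success", [
        (2, False, None),     # <3 attendance days: no nest
        (27, True, False),    # run below the 28-day success floor
        (30, True, True),
        (40, True, False),    # overdue incubation: not successful
    ])
    def test_run_length_rules(self, acfg, nest_days, expect_nest, expect_success):
        cfg = breeding_only_scenario(22 + nest_days, 1, propensity=1.1,
                                     fixed_nest_days=nest_days)
        fixes, _ = syn.gen_track(cfg, "g000", 2022)
        nest = tr.detect_nest(fixes, acfg)
        if not expect_nest:
            assert nest is None
        else:
            assert nest.run_length_days == nest_days
            assert nest.success is expect_success
            assert (nest.hatch_day is not None) is expect_success

    def test_invariance_to_shuffling_and_distant_flying_fixes(self, acfg):
        cfg = breeding_only_scenario(25, 1, propensity=1.1, fixed_nest_days=30)
        fixes, _ = syn.gen_track(cfg, "g000", 2022)
        base = tr.detect_nest(fixes, acfg)
        shuffled = fixes.sample(frac=1.0, random_state=0)
        extra = pd.DataFrame([_fix(f"2022-06-01 10:{m:02d}", 70.0, 40.0, speed=70.0,
                                   animal="g000") for m in range(5)])
        noisy = pd.concat([shuffled, extra], ignore_index=True)
        alt = tr.detect_nest(noisy, acfg)
        assert (alt.laying_day, alt.run_length_days, alt.success) == \
               (base.laying_day, base.run_length_days, base.success)


class TestRatiosAndIntervals:
    def _summaries(self, k, n, area="svalbard"):
        out = []
        for i in range(n):
            out.append(tr.BreedingSummary(f"g{i}", 2022, area, 140, attempted=i < k,
                                          laying_day=150 if i < k else None))
        return out

    @pytest.mark.parametrize("k,n,expected", [(37, 62, 0.597), (17, 28, 0.607), (0, 10, 0.0)])
    def test_breeding_propensity(self, k, n, expected):
        kk, nn, p = tr.breeding_propensity(self._summaries(k, n))
        assert (kk, nn) == (k, n)
        assert round(p, 3) == expected

    @pytest.mark.parametrize("k,n,expected", [(18, 36, 0.500), (9, 17, 0.529)])
    def test_nesting_success(self, k, n, expected):
        nests = [tr.NestRecord(f"g{i}", 2022, 78.0, 16.0, 150, 30 if i < k else 10,
                               success=i < k, hatch_day=None) for i in range(n)]
        kk, nn, p = tr.nesting_success(nests)
        assert (kk, nn) == (k, n) and round(p, 3) == expected
        assert tr.nesting_success([nests[0]])[2] == 1.0

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            tr.breeding_propensity([])
        with pytest.raises(ValueError):
            tr.nesting_success([])

    def test_pre_laying_interval(self):
        s = tr.BreedingSummary("g", 2022, "svalbard", 135, True, laying_day=152)
        assert tr.pre_laying_interval(s) == 17
        s2 = tr.BreedingSummary("g", 2022, "svalbard", 135, True, laying_day=135)
        assert tr.pre_laying_interval(s2) == 0
        s3 = tr.BreedingSummary("g", 2022, "svalbard", 140, True, laying_day=139)
        with pytest.raises(ValueError):
            tr.pre_laying_interval(s3)

    def test_relative_timing(self):
        from pinkfoot.onset import Qc, SpringOnsetRecord
        onset = SpringOnsetRecord("svalbard", 2022, "greenup", 160.0, 10, Qc.OK)
        assert tr.relative_timing(155, onset) == -5.0
        assert tr.relative_timing(160, onset) == 0.0
        for k in (-7, 3):
            shifted = SpringOnsetRecord("svalbard", 2022, "greenup", 160.0 + k, 10, Qc.OK)
            assert tr.relative_timing(155, shifted) == -5.0 - k
        with pytest.raises(ValueError):
            tr.relative_timing(155, onset, year=2021)


def test_visit_precedes_breeding_arrival(noiseless_scenario, acfg):
    fixes, _ = syn.gen_track(noiseless_scenario, "goose002", 2022)
    v = tr.visit_dates(fixes, tr.StopoverSite("trondelag", 63.5, 10.5), acfg)
    arr = tr.breeding_arrival(fixes, "svalbard", acfg)
    assert v.arrival_day <= arr
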