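"""Boat-noise detection gate: earliest crossing, censoring, distance."""

import math

import numpy as np
import pandas as pd
import pytest

from shoalsound import (
    Audiogram,
    BoatPass,
    BoatPassConfig,
    earliest_detection,
    limiting_factor,
    reaction_distance,
    synth_boat_pass,
)
from shoalsound.detectability import (
    CENSORED,
    DETECTED,
    NOISE_LIMITED,
    NOT_DETECTABLE,
    THRESHOLD_LIMITED,
    MPH_TO_MS,
)


def make_pass(levels_by_time: dict[int, float], speed_mph: float = 7.0) -> BoatPass:
    times = sorted(levels_by_time)
    frame = pd.DataFrame(
        {1000.0: [levels_by_time[t] for t in times]},
        index=pd.Index(times, name="time_rel_cpa_s"),
    )
    return BoatPass(speed_mph=speed_mph, levels=frame)


AUDIOGRAM = Audiogram({1000.0: 90.0})


class TestEarliestDetection:
    def test_constructed_crossing(self):
        """Rising levels cross the 100 dB background two seconds before CPA."""
        boat = make_pass({-4: 95.0, -3: 98.0, -2: 101.0, -1: 104.0, 0: 106.0})
        res = earliest_detection(boat, AUDIOGRAM, {1000.0: 100.0})[1000.0]
        assert res.status == DETECTED
        assert res.seconds_before_cpa == 2.0
        assert res.distance_at_detection == reaction_distance(2.0, 7.0)

    def test_gate_never_crossed_is_not_detectable(self):
        boat = make_pass({-4: 95.0, -3: 98.0, -2: 101.0, -1: 104.0, 0: 106.0})
        res = earliest_detection(boat, Audiogram({1000.0: 120.0}), {1000.0: 100.0})[1000.0]
        assert res.status == NOT_DETECTABLE
        assert res.seconds_before_cpa is None

    def test_exceeded_at_window_edge_is_censored(self):
        levels = {t: 110.0 for t in range(-30, 4)}
        res = earliest_detection(make_pass(levels), AUDIOGRAM, {1000.0: 100.0})[1000.0]
        assert res.status == CENSORED

    def test_equality_does_not_trigger(self):
        """'Exceeds' is strict: a level exactly at the gate is not detection."""
        boat = make_pass({-2: 100.0, -1: 100.0, 0: 101.0})
        res = earliest_detection(boat, AUDIOGRAM, {1000.0: 100.0})[1000.0]
        assert res.seconds_before_cpa == 0.0

    def test_missing_band_in_audiogram_errors(self):
        boat = make_pass({-1: 100.0, 0: 101.0})
        with pytest.raises(KeyError, match="1000"):
            earliest_detection(boat, Audiogram({500.0: 80.0}), {1000.0: 90.0})

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_closed_form_crossing(self, seed):
        """Detection on a synthetic pass equals the analytic gate crossing."""
        rng = np.random.default_rng(seed)
        speed = rng.uniform(5.0, 30.0)
        sl = rng.uniform(130.0, 160.0)
        gate = rng.uniform(95.0, 125.0)
        cpa = rng.uniform(1.0, 2.0)
        cfg = BoatPassConfig(speed_mph=speed, source_tol={1000.0: sl}, cpa_offset_m=cpa)
        table, _ = synth_boat_pass(cfg)
        boat = BoatPass(speed_mph=speed, levels=table)
        res = earliest_detection(boat, Audiogram({1000.0: gate}), {1000.0: gate})[1000.0]
        # analytic: exceed iff r(t) < r*; strict inequality at whole seconds
        r_star = 10 ** ((sl - gate) / 15.0)
        v = speed * MPH_TO_MS
        if r_star <= cpa:
            assert res.status == NOT_DETECTABLE
            return
        t_max = math.sqrt(r_star**2 - cpa**2) / v
        expected_warning = math.floor(t_max) if t_max != math.floor(t_max) else t_max - 1
        if expected_warning >= 30:
            assert res.status == CENSORED
        else:
            assert res.status == DETECTED
            assert res.seconds_before_cpa == expected_warning


class TestLimitingFactor:
    @pytest.mark.parametrize(
        "threshold, bg, expected",
        [
            (96.0, 90.0, THRESHOLD_LIMITED),
            (96.0, 104.0, NOISE_LIMITED),
            (96.0, 96.0, NOISE_LIMITED),  # tie rule
        ],
    )
    def test_cases(self, threshold, bg, expected):
        assert limiting_factor(Audiogram({1000.0: threshold}), bg, 1000.0) == expected


class TestReactionDistance:
    @pytest.mark.parametrize(
        "seconds, mph, metres",
        [(15, 7, 47), (15, 26.2, 176), (0, 17.4, 0)],
    )
    def test_published_anchor_distances(self, seconds, mph, metres):
        assert reaction_distance(seconds, mph) == metres

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            reaction_distance(-1.0, 7.0)

    def test_linear_in_both_arguments(self):
        base = 17.4 * MPH_TO_MS * 10
        assert reaction_distance(20, 17.4) == pytest.approx(2 * base, abs=1.0)
        assert reaction_distance(10, 34.8) == pytest.approx(2 * base, abs=1.0)


class TestMonotonicity:
    def test_raising_background_never_lengthens_warning(self):
        cfg = BoatPassConfig(speed_mph=17.4, source_tol={1000.0: 145.0})
        table, _ = synth_boat_pass(cfg)
        boat = BoatPass(speed_mph=17.4, levels=table)
        warnings = []
        for bg in (100.0, 105.0, 110.0, 115.0, 120.0):
            res = earliest_detection(boat, Audiogram({1000.0: 80.0}), {1000.0: bg})[1000.0]
            warnings.append(
                31.0 if res.status == CENSORED
                else -1.0 if res.status == NOT_DETECTABLE
                else res.seconds_before_cpa
            )
        assert all(a >= b for a, b in zip(warnings, warnings[1:]))

    def test_background_above_pass_maximum_never_detects(self):
        cfg = BoatPassConfig(speed_mph=7.0, source_tol={1000.0: 140.0}, cpa_offset_m=1.5)
        table, _ = synth_boat_pass(cfg)
        peak = table[1000.0].max()
        boat = BoatPass(speed_mph=7.0, levels=table)
        res = earliest_detection(boat, Audiogram({1000.0: 80.0}), {1000.0: peak + 1.0})[1000.0]
        assert res.status == NOT_DETECTABLE

    def test_faster_boat_detected_with_less_warning(self):
        """Same source spectrum: at any warning time a faster boat is farther away."""
        gate = 112.0
        warnings = {}
        for speed in (7.0, 17.4, 26.2):
            table, _ = synth_boat_pass(
                BoatPassConfig(speed_mph=speed, source_tol={1000.0: 140.0})
            )
            boat = BoatPass(speed_mph=speed, levels=table)
            res = earliest_detection(boat, Audiogram({1000.0: 80.0}), {1000.0: gate})[1000.0]
            warnings[speed] = res.seconds_before_cpa
        assert warnings[7.0] >= warnings[17.4] >= warnings[26.2]
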