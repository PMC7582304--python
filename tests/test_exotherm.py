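import numpy as np
import pandas as pd
import pytest

from cryoleaf.errors import DataError, ParameterError
from cryoleaf.exotherm import (
    DetectorParams,
    FreezeEvent,
    delta_series,
    detect_exotherms,
    freeze_durations,
    plant_event_spread,
)
from cryoleaf.thermal_io import ChannelMeta

from conftest import make_table


class TestDeltaSeries:
    def test_constant_series_gives_zero(self):
        d = delta_series(np.full(100, -5.0), lag_s=10, interval_s=2)
        assert np.allclose(d[5:], 0.0)
        assert np.isnan(d[:5]).all()

    def test_linear_cooling_closed_form(self):
        # -3 degC/h over a 10 s lag -> -3/360 degC
        t = np.arange(0, 3600, 2.0)
        series = 5.0 - 3.0 * t / 3600.0
        d = delta_series(series, lag_s=10, interval_s=2)
        assert np.allclose(d[5:], -3.0 / 360.0)

    def test_step_response(self):
        series = np.full(100, -3.0)
        series[50:] += 1.5
        d = delta_series(series, lag_s=10, interval_s=2)
        assert np.allclose(d[50:55], 1.5)
        assert np.allclose(d[55:], 0.0)

    def test_lag_shorter_than_interval_rejected(self):
        with pytest.raises(ParameterError):
            delta_series(np.zeros(10), lag_s=1, interval_s=2)

    def test_nan_gap_propagates(self):
        series = np.linspace(-1, -3, 50)
        series[20:25] = np.nan
        d = delta_series(series, lag_s=10, interval_s=2)
        assert np.isnan(d[20:30]).all()


def _night_trace(jump_at=None, jump=1.5, n=2000, start_c=2.0, rate_per_sample=-0.005):
    """Cooling trace with an optional exotherm-like step."""
    series = start_c + rate_per_sample * np.arange(n)
    if jump_at is not None:
        series[jump_at:] += jump
    return series


class TestDetectExotherms:
    def test_constant_subzero_trace_yields_nothing(self):
        table = make_table({"TC_1": np.full(500, -5.0)})
        assert detect_exotherms(table) == []

    def test_single_injected_jump_recovered(self):
        # trace cools through -2.6 degC and jumps by 1.5 there
        series = _night_trace()
        i_jump = int(np.argmax(series < -2.6))
        series[i_jump:] += 1.5
        table = make_table({"TC_1": series})
        events = detect_exotherms(table)
        assert len(events) == 1
        assert events[0].T_nucleation == pytest.approx(-2.6, abs=0.05)
        assert events[0].delta_T >= 1.0

    def test_two_jumps_within_refractory_merge(self):
        series = _night_trace(jump_at=800)
        series[800 + 150 :] += 1.5  # second jump 5 min later (2 s sampling)
        table = make_table({"TC_1": series})
        events = detect_exotherms(table)
        assert len(events) == 1

    def test_two_jumps_beyond_refractory_stay_separate(self):
        series = _night_trace(n=4000, jump_at=500)
        series[500 + 1200 :] += 1.5  # 40 min later > 30 min refractory
        table = make_table({"TC_1": series})
        events = detect_exotherms(table)
        assert len(events) == 2

    def test_warm_rise_rejected_by_subzero_guard(self):
        series = np.full(500, 3.0)
        series[200:] += 2.0
        table = make_table({"TC_1": series})
        assert detect_exotherms(table) == []

    def test_air_coincident_rise_vetoed(self):
        leaf = _night_trace(jump_at=900)
        air = np.full(2000, 1.0)
        air[898:] += 1.5  # ambient artifact within +-lag of the leaf rise
        table = make_table({"TC_1": leaf, "AIR": air}, roles={"AIR": "air_2m"})
        assert detect_exotherms(table) == []
        # without the coincident air rise the event is found
        table2 = make_table({"TC_1": leaf, "AIR": np.full(2000, 1.0)}, roles={"AIR": "air_2m"})
        assert len(detect_exotherms(table2)) == 1

    def test_no_leaf_channels_is_an_error(self):
        table = make_table({"AIR": np.zeros(100)}, roles={"AIR": "air_2m"})
        with pytest.raises(DataError):
            detect_exotherms(table)

    @pytest.mark.parametrize("thresholds", [(0.3, 0.6, 1.0, 2.0)])
    def test_threshold_monotonicity_for_separated_events(self, thresholds):
        # jumps of graded magnitude, spaced beyond the refractory window, so
        # each either passes or fails the threshold independently
        n = 8000  # 2 s sampling -> jumps >30 min apart
        series = np.full(n, -3.0)
        for at, size in [(1000, 0.4), (3000, 0.8), (5000, 1.5), (7000, 2.5)]:
            series[at:] += size
        series -= np.linspace(0, 6, n)  # keep the trace subzero throughout
        table = make_table({"TC_1": series})
        counts = [
            len(detect_exotherms(table, DetectorParams(threshold_c=th)))
            for th in thresholds
        ]
        assert counts == [4, 3, 2, 1]


# ---------------------------------------------------------------------------
# brute-force oracle: independent double-loop scan of the delta-T criterion
# ---------------------------------------------------------------------------

def brute_force_events(table, params):
    interval = table.nominal_interval_s
    k = int(round(params.lag_s / interval))
    n = len(table.time)

    air_hot = set()
    for cid in table.channels("air_2m") + table.channels("air_canopy"):
        a = table.column(cid)
        for t in range(k, n):
            d = a[t] - a[t - k]
            if np.isfinite(d) and d >= params.threshold_c:
                air_hot.add(t)

    out = []
    for cid in table.channels("leaf"):
        series = table.column(cid)
        flagged = []
        for t in range(k, n):
            d = series[t] - series[t - k]
            if not np.isfinite(d) or d < params.threshold_c:
                continue
            if params.require_subzero and not series[t - k] < 0:
                continue
            if any(abs(t - j) <= k for j in air_hot):
                continue
            flagged.append(t)
        max_gap = params.refractory_min * 60 / interval
        clusters = []
        for t in flagged:
            if clusters and t - clusters[-1][-1] <= max_gap:
                clusters[-1].append(t)
            else:
                clusters.append([t])
        for cluster in clusters:
            i0 = cluster[0]
            out.append(
                (
                    cid,
                    table.time[i0],
                    float(series[i0 - k]),
                    float(max(series[t] - series[t - k] for t in cluster)),
                )
            )
    return out


def random_fixture(rng, n=2000, with_air=True):
    """Random walk leaf traces with injected jumps, plateaus and gaps."""
    channels = {}
    roles = {}
    for j in range(rng.integers(1, 3)):
        series = -1.0 + np.cumsum(rng.normal(-0.001, 0.05, n))
        for _ in range(rng.integers(0, 4)):
            at = rng.integers(10, n - 10)
            series[at:] += rng.uniform(0.3, 2.0)
        if rng.random() < 0.3:
            g0 = rng.integers(0, n - 50)
            series[g0 : g0 + rng.integers(5, 40)] = np.nan
        channels[f"TC_{j + 1}"] = series
    if with_air and rng.random() < 0.5:
        air = 1.0 + np.cumsum(rng.normal(0, 0.03, n))
        if rng.random() < 0.5:
            air[rng.integers(10, n - 10) :] += rng.uniform(0.5, 1.5)
        channels["AIR"] = air
        roles["AIR"] = "air_2m"
    return make_table(channels, roles=roles)


def test_detector_matches_brute_force_scan():
    """Vectorized detector agrees exactly with an exhaustive double-loop
    scan of the delta-T criterion on randomized fixtures."""
    rng = np.random.default_rng(2024)
    params = DetectorParams()
    for _ in range(20):
        table = random_fixture(rng)
        got = [
            (e.channel_id, e.t_nucleation, e.T_nucleation, e.delta_T)
            for e in detect_exotherms(table, params)
        ]
        expected = brute_force_events(table, params)
        assert len(got) == len(expected)
        for g, x in zip(sorted(got), sorted(expected)):
            assert g[0] == x[0] and g[1] == x[1]
            assert g[2] == pytest.approx(x[2], abs=1e-12)
            assert g[3] == pytest.approx(x[3], abs=1e-12)


class TestFreezeDurations:
    def _fixture(self):
        # 2 s sampling from 21:00; crosses 0 downward at 22:00, nucleates at
        # 00:44 (exotherm jump), trend crosses 0 upward at 06:30
        n = 12 * 3600 // 2  # 21:00 -> 09:00
        t = np.arange(n) * 2.0
        series = np.empty(n)
        i_down = 3600 // 2  # 22:00
        i_nuc = (3 * 3600 + 44 * 60) // 2  # 00:44
        i_up = (9 * 3600 + 30 * 60) // 2  # 06:30
        series[:i_down] = np.linspace(2.0, 0.0, i_down)
        series[i_down:i_nuc] = np.linspace(0.0, -3.0, i_nuc - i_down) - 1e-9
        series[i_nuc:i_up] = np.linspace(-2.0, 0.0, i_up - i_nuc) - 1e-9
        series[i_up:] = np.linspace(0.0, 4.0, n - i_up) + 1e-9
        table = make_table({"TC_1": series}, start="2019-07-10 21:00:00")
        events = detect_exotherms(table)
        assert len(events) == 1
        return table, events[0]

    def test_supercooled_and_frozen_durations(self):
        table, event = self._fixture()
        done = freeze_durations(event, table)
        assert done.supercooling_min == pytest.approx(164, abs=0.5)
        assert done.duration_frozen_min == pytest.approx(346, abs=0.5)
        assert done.t_thaw > done.t_nucleation

    def test_open_intervals_left_missing(self):
        # nucleation-like jump on a trace that starts below zero and never thaws
        series = np.linspace(-2.5, -3.5, 1000)
        series[500:] += 1.2
        table = make_table({"TC_1": series})
        event = detect_exotherms(table)[0]
        done = freeze_durations(event, table)
        assert done.supercooling_min is None
        assert done.duration_frozen_min is None
        assert done.t_thaw is None


class TestPlantEventSpread:
    META = [
        ChannelMeta("TC_1", "leaf", plant_id="plant_1", leaf_id="a"),
        ChannelMeta("TC_2", "leaf", plant_id="plant_1", leaf_id="b"),
        ChannelMeta("TC_3", "leaf", plant_id="plant_1", leaf_id="c"),
    ]

    @staticmethod
    def _event(cid, when):
        return FreezeEvent(cid, pd.Timestamp(when), -2.5, 1.0)

    def test_three_leaves_spread(self):
        events = [
            self._event("TC_1", "2019-07-10 23:00:00"),
            self._event("TC_2", "2019-07-11 01:30:00"),
            self._event("TC_3", "2019-07-11 03:10:00"),
        ]
        out = plant_event_spread(events, self.META)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["spread_min"] == pytest.approx(250)
        assert row["n_leaves_frozen"] == 3

    def test_single_event_zero_spread(self):
        out = plant_event_spread([self._event("TC_1", "2019-07-10 23:00:00")], self.META)
        assert out.iloc[0]["spread_min"] == 0
        assert out.iloc[0]["n_leaves_frozen"] == 1

    def test_no_events_no_rows(self):
        assert plant_event_spread([], self.META).empty
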