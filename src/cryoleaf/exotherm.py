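"""Freezing-exotherm detection by differential thermal analysis (DTA).

When supercooled leaf water crystallizes, latent heat release produces a
sudden transient rise of leaf temperature — the freezing exotherm.  The
detector searches each leaf channel for temperature increases over a
short lag, ``ΔT(t) = T(t) − T(t − lag)``, with a 10 s lag by default,
and reports the ice nucleation temperature as the leaf temperature
immediately before the rise.

A rise is accepted as an exotherm only if the leaf was below 0 °C before
it (ice cannot nucleate above the melting point) and, when an air
channel is present, no coincident rise occurs in the air temperature —
sudden ambient warming affects leaf and air alike, whereas an exotherm
is confined to the freezing leaf.  Flags close together in time are
merged into a single event: in the field each leaf froze once per night,
so wobble on the freezing plateau must not be double counted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from cryoleaf.errors import DataError, ParameterError
from cryoleaf.thermal_io import ChannelMeta, SensorTable


@dataclass(frozen=True)
class DetectorParams:
    """Tuning of the ΔT exotherm detector.

    lag_s
        Lag of the temperature difference, seconds.
    threshold_c
        Minimum rise over the lag accepted as an exotherm, °C.  Must be
        well above sensor noise yet below the latent-heat rise.
    refractory_min
        Flags within this window merge into a single event, minutes.
    require_subzero
        Reject rises whose pre-rise temperature is at or above 0 °C.
    thaw_threshold_c
        Temperature whose first upward crossing after nucleation ends the
        frozen period, °C.
    """

    lag_s: float = 10.0
    threshold_c: float = 0.5
    refractory_min: float = 30.0
    require_subzero: bool = True
    thaw_threshold_c: float = 0.0

    def __post_init__(self) -> None:
        if self.lag_s <= 0:
            raise ParameterError("lag_s must be positive")
        if self.threshold_c <= 0:
            raise ParameterError("threshold_c must be positive")


@dataclass
class FreezeEvent:
    """One detected freezing exotherm on one leaf channel."""

    channel_id: str
    t_nucleation: pd.Timestamp
    T_nucleation: float
    delta_T: float
    t_thaw: Optional[pd.Timestamp] = None
    duration_frozen_min: Optional[float] = None
    supercooling_min: Optional[float] = None


def _lag_samples(lag_s: float, interval_s: float) -> int:
    """Lag expressed in samples; nearest sample within half-interval tolerance."""
    if lag_s < interval_s:
        raise ParameterError(f"lag {lag_s} s shorter than sampling interval {interval_s} s")
    k = int(round(lag_s / interval_s))
    if abs(k * interval_s - lag_s) > interval_s / 2:
        raise ParameterError(f"lag {lag_s} s not representable at interval {interval_s} s")
    return k


def delta_series(series: np.ndarray, lag_s: float, interval_s: float) -> np.ndarray:
    """Lagged temperature difference ΔT(t) = T(t) − T(t − lag).

    The first ``lag`` of the record has no lagged partner and is NaN;
    differences across logger gaps (NaN samples) are NaN as well.
    """
    series = np.asarray(series, dtype=float)
    k = _lag_samples(lag_s, interval_s)
    out = np.full_like(series, np.nan)
    out[k:] = series[k:] - series[:-k]
    return out


def detect_exotherms(table: SensorTable, params: DetectorParams = DetectorParams()) -> list[FreezeEvent]:
    """Detect freezing exotherms on every leaf channel of a regular table.

    Returns events per channel in time order.  Durations
    (``supercooling_min``, ``duration_frozen_min``, ``t_thaw``) are filled
    in by :func:`freeze_durations`.
    """
    leaf_ids = table.channels("leaf")
    if not leaf_ids:
        raise DataError("table has no leaf channels")
    interval = table.nominal_interval_s
    k = _lag_samples(params.lag_s, interval)

    # air-coincidence veto: any air channel rising by >= threshold within +-lag
    air_ids = table.channels("air_2m") + table.channels("air_canopy")
    air_flag = np.zeros(len(table.time), dtype=bool)
    for cid in air_ids:
        d_air = delta_series(table.column(cid), params.lag_s, interval)
        air_flag |= d_air >= params.threshold_c
    if air_flag.any():
        # dilate by +-k samples
        idx = np.flatnonzero(air_flag)
        veto = np.zeros(len(air_flag), dtype=bool)
        for i in idx:
            veto[max(0, i - k) : i + k + 1] = True
        air_flag = veto

    refractory_samples = params.refractory_min * 60.0 / interval
    events: list[FreezeEvent] = []
    for cid in leaf_ids:
        series = table.column(cid)
        d = delta_series(series, params.lag_s, interval)
        with np.errstate(invalid="ignore"):
            flags = d >= params.threshold_c
            if params.require_subzero:
                pre = np.full_like(series, np.nan)
                pre[k:] = series[:-k]
                flags &= pre < 0.0
        flags &= ~air_flag
        for run in _cluster(np.flatnonzero(flags), refractory_samples):
            i0 = run[0]
            events.append(
                FreezeEvent(
                    channel_id=cid,
                    t_nucleation=table.time[i0],
                    T_nucleation=float(series[i0 - k]),
                    delta_T=float(np.nanmax(d[run])),
                )
            )
    return events


def _cluster(indices: np.ndarray, max_gap: float) -> list[np.ndarray]:
    """Split flagged sample indices into events: successive flags closer than
    ``max_gap`` samples belong to the same event."""
    if len(indices) == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > max_gap) + 1
    return np.split(indices, breaks)


def freeze_durations(event: FreezeEvent, table: SensorTable, params: DetectorParams = DetectorParams()) -> FreezeEvent:
    """Complete an event with supercooling and frozen durations.

    The supercooled period runs from the last downward crossing of 0 °C
    before nucleation to the nucleation instant; the frozen period runs
    from nucleation to the first subsequent upward crossing of
    ``thaw_threshold_c`` (morning warm-up).  Either bound may lie outside
    the record, in which case the corresponding duration stays missing.
    """
    series = table.column(event.channel_id)
    t = table.time
    i_nuc = int(t.searchsorted(event.t_nucleation))
    if i_nuc >= len(t) or t[i_nuc] != event.t_nucleation:
        raise DataError("event t_nucleation not on this channel's time base")

    supercooling = None
    with np.errstate(invalid="ignore"):
        down = np.flatnonzero((series[:-1] >= 0.0) & (series[1:] < 0.0)) + 1
    down = down[down <= i_nuc]
    if len(down):
        supercooling = (t[i_nuc] - t[down[-1]]).total_seconds() / 60.0

    t_thaw = None
    frozen = None
    thr = params.thaw_threshold_c
    with np.errstate(invalid="ignore"):
        up = np.flatnonzero((series[:-1] <= thr) & (series[1:] > thr)) + 1
    up = up[up > i_nuc]
    if len(up):
        t_thaw = t[up[0]]
        frozen = (t_thaw - t[i_nuc]).total_seconds() / 60.0

    return replace(event, t_thaw=t_thaw, duration_frozen_min=frozen, supercooling_min=supercooling)


def plant_event_spread(events: list[FreezeEvent], meta: list[ChannelMeta]) -> pd.DataFrame:
    """Per plant and night: spread of nucleation times across its leaves.

    In the field, leaves of one individual froze independently, hours
    apart; the spread (max − min nucleation time, minutes) quantifies
    that.  A night is labelled by the date of its evening (an event at
    00:44 belongs to the previous evening's night).  Plants without any
    event on a night contribute no row.
    """
    by_channel = {m.channel_id: m for m in meta}
    rows = []
    for ev in events:
        m = by_channel.get(ev.channel_id)
        if m is None or m.role != "leaf":
            raise DataError(f"event channel {ev.channel_id!r} is not a known leaf channel")
        night = (ev.t_nucleation - pd.Timedelta(hours=12)).date()
        rows.append({"plant_id": m.plant_id, "night": night, "t": ev.t_nucleation})
    if not rows:
        return pd.DataFrame(columns=["plant_id", "night", "spread_min", "n_leaves_frozen"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["plant_id", "night"])["t"]
        .agg(spread_min=lambda s: (s.max() - s.min()).total_seconds() / 60.0, n_leaves_frozen="count")
        .reset_index()
    )
    return out


def events_to_frame(events: list[FreezeEvent]) -> pd.DataFrame:
    """Events as a DataFrame mirroring the event CSV columns."""
    return pd.DataFrame(
        [
            {
                "channel_id": e.channel_id,
                "t_nucleation": e.t_nucleation,
                "T_nucleation": e.T_nucleation,
                "delta_T": e.delta_T,
                "t_thaw": e.t_thaw,
                "duration_frozen_min": e.duration_frozen_min,
                "supercooling_min": e.supercooling_min,
            }
            for e in events
        ]
    )
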