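"""Campaign-level frost microclimate statistics.

At high elevation the air temperature is a poor proxy for leaf
temperature: under clear skies leaves radiate to the night sky and drop
several degrees below the air, while snow cover clamps them near 0 °C.
This module computes the campaign summaries that quantify that
decoupling: daily extrema, the frequency of frost nights at the leaf,
leaf−air temperature depressions, and snow-cover classification from
the damped daily amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cryoleaf.errors import DataError, ParameterError
from cryoleaf.thermal_io import SensorTable


@dataclass(frozen=True)
class NightWindow:
    """Clock-hour window defining a night, evening start to morning end.

    The default 18:00 → 09:00 generously brackets the span over which
    leaf freezing events were observed in the field (late evening to
    shortly after six in the morning).
    """

    start_hour: int = 18
    end_hour: int = 9

    def __post_init__(self) -> None:
        if not (0 <= self.start_hour < 24 and 0 <= self.end_hour < 24):
            raise ParameterError("hours must be in [0, 24)")
        if self.start_hour == self.end_hour:
            raise ParameterError("night window must be nonempty")


@dataclass
class CampaignSummary:
    """Headline frost statistics of one campaign."""

    frost_night_rate_mean: float
    frost_night_rate_sd: float
    frost_night_rate_per_channel: dict = field(default_factory=dict)
    max_depression_vs_air2m_c: float = np.nan
    max_depression_vs_canopy_c: float = np.nan
    pct_leaf_min_below_air_min: float = np.nan
    snow_days: pd.DataFrame | None = None


def _night_labels(time: pd.DatetimeIndex, window: NightWindow):
    """Boolean in-window mask and per-sample night label (date of the evening)."""
    hours = time.hour
    s, e = window.start_hour, window.end_hour
    if s > e:  # window spans midnight
        in_window = (hours >= s) | (hours < e)
        night = time.normalize().where(hours >= s, time.normalize() - pd.Timedelta(days=1))
    else:
        in_window = (hours >= s) & (hours < e)
        night = time.normalize()
    return np.asarray(in_window), pd.DatetimeIndex(night).date


def daily_extrema(table: SensorTable) -> pd.DataFrame:
    """Per-channel, per-calendar-day minimum and maximum with timestamps.

    Days on which a channel recorded nothing are omitted for that channel.
    """
    df = table.to_frame()
    day = df.index.normalize()
    rows = []
    for cid in df.columns:
        s = df[cid]
        for d, grp in s.groupby(day):
            if grp.notna().sum() == 0:
                continue
            rows.append(
                {
                    "channel_id": cid,
                    "day": d.date(),
                    "min_c": float(grp.min()),
                    "t_min": grp.idxmin(),
                    "max_c": float(grp.max()),
                    "t_max": grp.idxmax(),
                }
            )
    return pd.DataFrame(rows, columns=["channel_id", "day", "min_c", "t_min", "max_c", "t_max"])


def _night_minima(table: SensorTable, channel_ids, window: NightWindow) -> pd.DataFrame:
    """Per-night minimum per channel, nights labelled by their evening date."""
    in_window, night = _night_labels(table.time, window)
    df = table.to_frame()[list(channel_ids)].loc[in_window]
    return df.groupby(np.asarray(night)[in_window]).min()


def frost_night_rate(table: SensorTable, window: NightWindow = NightWindow()):
    """Fraction of nights on which each leaf channel dropped below 0 °C.

    A frost night is a night whose within-window minimum is strictly
    below 0 °C ("dropped below").  Returns the mean and SD of the
    per-channel fractions (aggregation across sensors, the only reading
    that yields a spread) plus the fractions themselves.
    """
    leaf_ids = table.channels("leaf")
    if not leaf_ids:
        raise DataError("table has no leaf channels")
    minima = _night_minima(table, leaf_ids, window)
    if minima.empty:
        raise DataError("no nights in record")
    fractions = (minima < 0.0).mean(axis=0)
    per_channel = {cid: float(fractions[cid]) for cid in leaf_ids}
    vals = np.array(list(per_channel.values()))
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd, per_channel


def depression(table: SensorTable, reference_role: str = "air_2m", window: NightWindow = NightWindow()):
    """Nocturnal leaf−air temperature depression.

    Pointwise difference T_leaf − T_ref at matched timestamps, minimized
    over each night window per leaf channel.  Negative values mean the
    leaf was colder than the reference air.  Returns (per-night table,
    campaign minimum).
    """
    refs = table.channels(reference_role)
    if not refs:
        raise DataError(f"no channel with role {reference_role!r}")
    ref = table.column(refs[0])
    leaf_ids = table.channels("leaf")
    if not leaf_ids:
        raise DataError("table has no leaf channels")

    in_window, night = _night_labels(table.time, window)
    diffs = pd.DataFrame(
        {cid: table.column(cid) - ref for cid in leaf_ids}, index=table.time
    ).loc[in_window]
    per_night = diffs.groupby(np.asarray(night)[in_window]).min()
    campaign_min = float(np.nanmin(per_night.to_numpy())) if per_night.size else np.nan
    return per_night, campaign_min


def snow_cover_days(table: SensorTable, amplitude_threshold_c: float = 1.0, band_c: float = 1.0) -> pd.DataFrame:
    """Classify snow-covered days per leaf/soil channel.

    Snow insulates the sensor near the melting point: a day is flagged
    covered iff its amplitude (max − min) is strictly below
    ``amplitude_threshold_c`` and its mean lies within ±``band_c`` of
    0 °C.  Air channels are not classified.
    """
    ids = table.channels("leaf") + table.channels("soil")
    if not ids:
        raise DataError("no leaf or soil channels")
    df = table.to_frame()[ids]
    day = df.index.normalize()
    grouped = df.groupby(day)
    amp = grouped.max() - grouped.min()
    mean = grouped.mean()
    flags = (amp < amplitude_threshold_c) & (mean.abs() <= band_c)
    flags.index = [d.date() for d in flags.index]
    return flags


def summarize_campaign(table: SensorTable, window: NightWindow = NightWindow()) -> CampaignSummary:
    """All headline statistics of a campaign in one pass."""
    mean, sd, per_channel = frost_night_rate(table, window)
    summary = CampaignSummary(
        frost_night_rate_mean=mean,
        frost_night_rate_sd=sd,
        frost_night_rate_per_channel=per_channel,
    )
    for role, attr in (("air_2m", "max_depression_vs_air2m_c"), ("air_canopy", "max_depression_vs_canopy_c")):
        if table.channels(role):
            _, campaign_min = depression(table, role, window)
            setattr(summary, attr, campaign_min)

    # share of nights on which the leaf minimum undercut the 2 m air minimum
    if table.channels("air_2m"):
        leaf_ids = table.channels("leaf")
        air_id = table.channels("air_2m")[0]
        minima = _night_minima(table, leaf_ids + [air_id], window)
        below = minima[leaf_ids].lt(minima[air_id], axis=0)
        summary.pct_leaf_min_below_air_min = float(100.0 * below.to_numpy().mean())

    summary.snow_days = snow_cover_days(table)
    return summary
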