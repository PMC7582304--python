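"""Reading, validation and regularization of thermocouple campaign logs.

A campaign log is a CSV with one ISO 8601 ``timestamp`` column plus one
column per thermocouple channel, accompanied by a channel-metadata CSV
that assigns every channel a role (``leaf``, ``air_2m``, ``air_canopy``
or ``soil``) and, for leaf channels, the plant and leaf it is attached
to.  Timestamps are local clock time at the site; no timezone handling
is applied.

Missing values are empty CSV cells and NaN in memory — never a sentinel
temperature.  Regularization assigns each grid instant the *nearest*
recorded sample (within half a grid step) rather than interpolating, so
short transients such as freezing exotherms are preserved verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from cryoleaf.errors import DataError, FormatError, MetadataError, ParameterError

logger = logging.getLogger(__name__)

ROLES = ("leaf", "air_2m", "air_canopy", "soil")

#: physically plausible range for field thermocouples, °C
TEMP_RANGE_C = (-60.0, 60.0)


@dataclass(frozen=True)
class ChannelMeta:
    """Identity and role of one thermocouple channel."""

    channel_id: str
    role: str
    plant_id: Optional[str] = None
    leaf_id: Optional[str] = None
    depth_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise MetadataError(f"unknown role {self.role!r} for channel {self.channel_id!r}")
        has_plant = self.plant_id is not None and self.leaf_id is not None
        if self.role == "leaf" and not has_plant:
            raise MetadataError(f"leaf channel {self.channel_id!r} needs plant_id and leaf_id")
        if self.role != "leaf" and (self.plant_id is not None or self.leaf_id is not None):
            raise MetadataError(f"plant_id/leaf_id only allowed for leaf channels ({self.channel_id!r})")


@dataclass
class SensorTable:
    """Multi-channel temperature series on a common time base.

    Parameters
    ----------
    time
        Strictly increasing sample instants (seconds resolution).
    values
        Array ``(n_samples, n_channels)`` of temperatures in °C; NaN marks
        missing samples.
    meta
        One :class:`ChannelMeta` per column, in column order.
    nominal_interval_s
        Nominal sampling interval in seconds (0.5 s⁻¹ logging → 2 s).
    """

    time: pd.DatetimeIndex
    values: np.ndarray
    meta: list[ChannelMeta]
    nominal_interval_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D [time x channel] array")
        if len(self.time) != self.values.shape[0]:
            raise DataError("timestamp count does not match value rows")
        if self.values.shape[1] != len(self.meta):
            raise DataError("channel count does not match metadata length")
        if len(self.time) == 0:
            raise DataError("empty sensor table")
        dt = np.diff(self.time.asi8)
        if np.any(dt <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.nominal_interval_s <= 0:
            raise DataError("nominal_interval_s must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < TEMP_RANGE_C[0] or finite.max() > TEMP_RANGE_C[1]):
            raise DataError(f"temperatures outside plausible range {TEMP_RANGE_C} °C")

    # -- convenience accessors -------------------------------------------------

    @property
    def channel_ids(self) -> list[str]:
        return [m.channel_id for m in self.meta]

    def column(self, channel_id: str) -> np.ndarray:
        """Return one channel as a 1-D float array (view)."""
        try:
            j = self.channel_ids.index(channel_id)
        except ValueError:
            raise MetadataError(f"no channel {channel_id!r}") from None
        return self.values[:, j]

    def channels(self, role: str) -> list[str]:
        """Channel ids with a given role."""
        return [m.channel_id for m in self.meta if m.role == role]

    def meta_for(self, channel_id: str) -> ChannelMeta:
        for m in self.meta:
            if m.channel_id == channel_id:
                return m
        raise MetadataError(f"no channel {channel_id!r}")

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame indexed by time, columns = channel ids."""
        return pd.DataFrame(self.values, index=self.time, columns=self.channel_ids)


def read_channel_meta(meta_path) -> list[ChannelMeta]:
    """Read a channel-metadata CSV (channel_id, role, plant_id, leaf_id, depth_cm)."""
    df = pd.read_csv(meta_path, dtype={"channel_id": str, "plant_id": str, "leaf_id": str})
    if "channel_id" not in df.columns or "role" not in df.columns:
        raise FormatError("metadata CSV needs channel_id and role columns")
    metas = []
    for _, row in df.iterrows():
        def opt(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v) else v
        depth = opt("depth_cm")
        metas.append(
            ChannelMeta(
                channel_id=str(row["channel_id"]),
                role=str(row["role"]),
                plant_id=opt("plant_id"),
                leaf_id=opt("leaf_id"),
                depth_cm=float(depth) if depth is not None else None,
            )
        )
    return metas


def read_sensor_log(path, meta_path) -> SensorTable:
    """Read a campaign log CSV plus channel metadata into a :class:`SensorTable`.

    Rows whose timestamp cannot be parsed are dropped (count logged).
    Every channel column must be described by the metadata; extra metadata
    rows for channels absent from the CSV are ignored.
    """
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise FormatError("sensor log must have a 'timestamp' column")
    channel_cols = [c for c in df.columns if c != "timestamp"]
    if not channel_cols:
        raise FormatError("sensor log has no channel columns")

    metas = {m.channel_id: m for m in read_channel_meta(meta_path)}
    unmapped = [c for c in channel_cols if c not in metas]
    if unmapped:
        raise MetadataError(f"channels missing from metadata: {unmapped}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        logger.warning("dropped %d rows with unparseable timestamps", int(bad.sum()))
        df = df.loc[~bad]
        ts = ts.loc[~bad]
    if len(df) == 0:
        raise DataError("no rows with valid timestamps")

    time = pd.DatetimeIndex(ts).floor("s")
    values = df[channel_cols].to_numpy(dtype=float)
    interval = _nominal_interval(time)
    return SensorTable(time=time, values=values, meta=[metas[c] for c in channel_cols], nominal_interval_s=interval)


def write_sensor_log(table: SensorTable, path, meta_path=None) -> None:
    """Write a table back to the CSV formats read by :func:`read_sensor_log`."""
    df = table.to_frame()
    df.insert(0, "timestamp", df.index.strftime("%Y-%m-%dT%H:%M:%S"))
    df.to_csv(path, index=False)
    if meta_path is not None:
        rows = [
            {
                "channel_id": m.channel_id,
                "role": m.role,
                "plant_id": m.plant_id,
                "leaf_id": m.leaf_id,
                "depth_cm": m.depth_cm,
            }
            for m in table.meta
        ]
        pd.DataFrame(rows).to_csv(meta_path, index=False)


def _nominal_interval(time: pd.DatetimeIndex) -> float:
    if len(time) < 2:
        return 1.0
    return float(np.median(np.diff(time.asi8)) / 1e9)


def regularize(table: SensorTable, target_interval_s: float) -> SensorTable:
    """Resample to a regular grid by nearest-sample assignment.

    Each grid instant takes the value of the nearest recorded sample if one
    lies within ``target_interval_s / 2``; otherwise it stays missing, so
    logger gaps remain gaps.  No value is ever interpolated or averaged:
    the output values are a subset of the input values.
    """
    if target_interval_s <= 0:
        raise ParameterError("target_interval_s must be positive")
    t_ns = table.time.asi8.astype(np.int64)
    step_ns = int(round(target_interval_s * 1e9))
    grid = np.arange(t_ns[0], t_ns[-1] + 1, step_ns)

    # nearest input sample for every grid point
    idx = np.searchsorted(t_ns, grid)
    idx = np.clip(idx, 1, len(t_ns) - 1)
    left, right = t_ns[idx - 1], t_ns[idx]
    nearest = np.where(np.abs(grid - left) <= np.abs(right - grid), idx - 1, idx)
    dist = np.abs(grid - t_ns[nearest])
    ok = dist <= step_ns // 2

    out = np.full((len(grid), table.values.shape[1]), np.nan)
    out[ok] = table.values[nearest[ok]]
    return SensorTable(
        time=pd.DatetimeIndex(grid.astype("datetime64[ns]")),
        values=out,
        meta=list(table.meta),
        nominal_interval_s=float(target_interval_s),
    )
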