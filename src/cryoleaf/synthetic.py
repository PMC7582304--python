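"""Synthetic campaign data with the statistical structure of the field study.

The generator is phenomenological, not an energy-balance model: it
reproduces the *measured* structure of a high-elevation campaign so
that every downstream estimator can be validated against known ground
truth.  Emulated features:

* a sinusoidal diel air cycle with a mild nocturnal trough;
* radiative leaf-below-air depressions on clear nights, deep enough on
  frost nights that supercooled leaves reach their nucleation
  temperature (drawn from a normal distribution around −2.6 °C,
  SD 0.9 °C, truncated below 0 °C);
* freezing exotherms: an abrupt rise of ≥ 1 °C within 10 s to a plateau
  just below 0 °C, relaxing exponentially back to the cooling trend;
* leaves of one plant nucleating independently, hours apart;
* snow nights clamping leaf and soil temperatures near 0 °C with
  sub-0.5 °C amplitude;
* a damped, lagged, near-0 °C-floored soil channel (the buried shoot's
  thermal refuge);
* Gaussian sensor noise everywhere.

Sibling generators produce Boltzmann-shaped viability assays,
diameter-biased cell-outline pairs, and infrared stacks with a single
brindled-then-homogeneous freezing event per leaf region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from cryoleaf.errors import ParameterError
from cryoleaf.thermal_io import ChannelMeta, SensorTable
from cryoleaf.freezing_resistance import BoltzmannParams, boltzmann
from cryoleaf.cytorrhysis import CellOutline
from cryoleaf.idta import FrameStack

SECONDS_PER_DAY = 86400
CAMPAIGN_START = "2019-07-01 12:00:00"  # noon start so each night is contiguous

# diel air cycle: maximum 7 degC at 14:00, trough 1 degC at 02:00
AIR_MEAN_C = 4.0
AIR_AMPLITUDE_C = 3.0
AIR_PEAK_HOUR = 14.0

# exotherm shape
EXOTHERM_RISE_S = 10.0
EXOTHERM_MIN_RISE_C = 1.0
EXOTHERM_PLATEAU_C = -0.3

# frost-night depressions are drawn deep enough that the nucleation draw is
# almost surely reached (leaf trend minimum <= -5 degC)
FROST_DEPRESSION_MIN_C = 6.5
CLEAR_DEPRESSION_RANGE_C = (0.1, 0.6)


@dataclass(frozen=True)
class CampaignConfig:
    """Study conditions of a synthetic thermocouple campaign.

    Defaults mirror the field statistics of the study site: 4 plants x 3
    leaf thermocouples, 2 s sampling, ice nucleation around -2.6 +- 0.9 degC,
    62% frost-night probability per leaf and night, and a deepest
    leaf-below-air depression of 9.3 degC.
    """

    n_nights: int = 10
    n_plants: int = 4
    leaves_per_plant: int = 3
    sampling_interval_s: float = 2.0
    nucleation_temp_mean_c: float = -2.6
    nucleation_temp_sd_c: float = 0.9
    frost_night_prob: float = 0.62
    max_depression_c: float = 9.3
    noise_sd_c: float = 0.05
    snow_nights: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nights < 1 or self.n_plants < 1 or self.leaves_per_plant < 1:
            raise ParameterError("counts must be >= 1")
        if not 0 <= self.frost_night_prob <= 1:
            raise ParameterError("frost_night_prob must lie in [0, 1]")
        if self.nucleation_temp_sd_c < 0 or self.noise_sd_c < 0:
            raise ParameterError("standard deviations must be >= 0")
        if self.sampling_interval_s <= 0:
            raise ParameterError("sampling_interval_s must be positive")
        if self.max_depression_c < 0:
            raise ParameterError("max_depression_c must be >= 0")
        object.__setattr__(self, "snow_nights", frozenset(int(n) for n in self.snow_nights))


@dataclass(frozen=True)
class TrueFreezeEvent:
    """Ground-truth nucleation of one leaf on one night."""

    channel_id: str
    t_nucleation: pd.Timestamp
    T_nucleation: float
    t_thaw: Optional[pd.Timestamp]


@dataclass
class GroundTruth:
    """Generator ground truth for recovery tests."""

    events: list[TrueFreezeEvent]
    night_frost_flags: np.ndarray  # (n_nights, n_leaf_channels) bool
    snow_flags: np.ndarray  # (n_nights,) bool
    leaf_channel_ids: list[str] = field(default_factory=list)


def _truncated_normal_below_zero(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from N(mean, sd) conditioned on < 0 (ice needs subzero)."""
    if sd == 0:
        return min(mean, -1e-9)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x < 0:
            return x
    raise RuntimeError("truncated normal rejection failed")  # pragma: no cover


def _depression_profile(t_sec: np.ndarray, t_start: float, t_peak: float, t_end: float) -> np.ndarray:
    """Raised-cosine bump: 0 outside [t_start, t_end], 1 at t_peak."""
    s = np.zeros_like(t_sec)
    rise = (t_sec >= t_start) & (t_sec <= t_peak)
    fall = (t_sec > t_peak) & (t_sec <= t_end)
    s[rise] = 0.5 - 0.5 * np.cos(np.pi * (t_sec[rise] - t_start) / (t_peak - t_start))
    s[fall] = 0.5 + 0.5 * np.cos(np.pi * (t_sec[fall] - t_peak) / (t_end - t_peak))
    return s


def simulate_campaign(config: CampaignConfig = CampaignConfig()) -> tuple[SensorTable, GroundTruth]:
    """Simulate a multi-night thermocouple campaign.

    Returns the sensor table (leaf channels per plant, 2 m air, canopy
    air, soil) and the ground truth of injected freezing events.  Output
    is bit-identical for identical config (single seeded RNG, fixed draw
    order).
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sampling_interval_s
    n_samples = int(round(config.n_nights * SECONDS_PER_DAY / dt)) + 1
    t_sec = np.arange(n_samples) * dt
    hours = (12.0 + t_sec / 3600.0) % 24.0  # clock hour (campaign starts at noon)

    air = AIR_MEAN_C + AIR_AMPLITUDE_C * np.cos(2 * np.pi * (hours - AIR_PEAK_HOUR) / 24.0)
    soil = 1.0 + 0.8 * np.cos(2 * np.pi * (hours - 17.0) / 24.0)  # damped, lagged, floored near 0

    n_leaves = config.n_plants * config.leaves_per_plant
    leaf_ids = []
    meta = []
    for p in range(config.n_plants):
        for l in range(config.leaves_per_plant):
            cid = f"TC_{p + 1}_{l + 1}"
            leaf_ids.append(cid)
            meta.append(ChannelMeta(cid, "leaf", plant_id=f"plant_{p + 1}", leaf_id=f"leaf_{l + 1}"))
    meta.append(ChannelMeta("AIR_2M", "air_2m"))
    meta.append(ChannelMeta("AIR_CANOPY", "air_canopy"))
    meta.append(ChannelMeta("SOIL_5CM", "soil", depth_cm=5.0))

    snow_flags = np.array([n in config.snow_nights for n in range(config.n_nights)])
    frost_flags = np.zeros((config.n_nights, n_leaves), dtype=bool)
    leaf_values = np.tile(air, (n_leaves, 1))
    dep_sum = np.zeros(n_samples)  # for the canopy channel

    # draw per-(night, leaf) frost states and depressions up front, then pin
    # the single deepest depression to max_depression_c so the campaign
    # minimum matches the configured extreme exactly
    frost_draw = rng.random((config.n_nights, n_leaves)) < config.frost_night_prob
    dep_peaks = np.zeros((config.n_nights, n_leaves))
    for night in range(config.n_nights):
        if snow_flags[night]:
            continue
        for j in range(n_leaves):
            if frost_draw[night, j]:
                dep_peaks[night, j] = rng.uniform(FROST_DEPRESSION_MIN_C, config.max_depression_c)
            else:
                dep_peaks[night, j] = rng.uniform(*CLEAR_DEPRESSION_RANGE_C)
    frost_cells = np.argwhere(frost_draw & ~snow_flags[:, None])
    if len(frost_cells) and config.max_depression_c >= FROST_DEPRESSION_MIN_C:
        deepest = frost_cells[np.argmax(dep_peaks[tuple(frost_cells.T)])]
        dep_peaks[tuple(deepest)] = config.max_depression_c

    events: list[TrueFreezeEvent] = []
    time_index = pd.date_range(CAMPAIGN_START, periods=n_samples, freq=pd.Timedelta(seconds=dt))
    k_rise = max(int(round(EXOTHERM_RISE_S / dt)), 1)

    for night in range(config.n_nights):
        base = night * SECONDS_PER_DAY
        t_start = base + 7 * 3600.0  # 19:00
        t_end = base + 20 * 3600.0  # 08:00 next morning
        win = slice(
            int(np.searchsorted(t_sec, t_start)),
            int(np.searchsorted(t_sec, t_end, side="right")),
        )
        if snow_flags[night]:
            # snow clamp from dusk; if the next night is snowy too the pack
            # persists through the day, otherwise the leaf blends back to the
            # clear-sky trend over 30 min in the morning
            clamp_lo = int(np.searchsorted(t_sec, base + 6 * 3600.0))  # 18:00
            if (night + 1) in config.snow_nights:
                clamp_hi = int(np.searchsorted(t_sec, base + 30 * 3600.0))  # 18:00 next day
                blend_hi = clamp_hi
            else:
                clamp_hi = int(np.searchsorted(t_sec, base + 21 * 3600.0))  # 09:00
                blend_hi = int(np.searchsorted(t_sec, base + 21.5 * 3600.0))
            for j in range(n_leaves):
                leaf_values[j, clamp_lo:clamp_hi] = 0.15
                w = np.linspace(0.0, 1.0, blend_hi - clamp_hi, endpoint=False)
                leaf_values[j, clamp_hi:blend_hi] = 0.15 + w * (air[clamp_hi:blend_hi] - 0.15)
            soil[clamp_lo:blend_hi] = 0.1
            continue

        for j in range(n_leaves):
            t_peak = base + rng.uniform(12.5, 15.5) * 3600.0  # 00:30-03:30
            profile = _depression_profile(t_sec[win], t_start, t_peak, t_end)
            dep = dep_peaks[night, j] * profile
            trend_night = air[win] - dep  # clear-sky cooling trend, pre-exotherm
            leaf_values[j, win] = trend_night
            dep_sum[win] += dep

            if not frost_draw[night, j]:
                continue
            frost_flags[night, j] = True
            theta = _truncated_normal_below_zero(
                rng, config.nucleation_temp_mean_c, config.nucleation_temp_sd_c
            )
            below = np.flatnonzero(trend_night < theta)
            if len(below) == 0:
                continue  # this leaf never supercooled to its threshold
            i_loc = int(below[0])
            i_n = win.start + i_loc
            plateau = max(theta + EXOTHERM_MIN_RISE_C, EXOTHERM_PLATEAU_C)
            # linear rise over <= 10 s
            steps = np.arange(1, k_rise + 1)
            leaf_values[j, i_n + 1 : i_n + k_rise + 1] = theta + (plateau - theta) * steps / k_rise
            # exponential relaxation back to the cooling trend
            tau = rng.uniform(200.0, 600.0)
            i0_loc = i_loc + k_rise
            n_decay = min(int(8 * tau / dt), len(trend_night) - i0_loc - 1)
            decay_t = np.arange(1, n_decay + 1) * dt
            excess = (plateau - trend_night[i0_loc]) * np.exp(-decay_t / tau)
            lo = win.start + i0_loc + 1
            leaf_values[j, lo : lo + n_decay] = trend_night[i0_loc + 1 : i0_loc + 1 + n_decay] + excess
            # thaw: first upward crossing of 0 degC of the clean morning trend
            after = np.flatnonzero((trend_night[i_loc:-1] < 0) & (trend_night[i_loc + 1 :] >= 0))
            t_thaw = time_index[i_n + 1 + int(after[0])] if len(after) else None
            events.append(
                TrueFreezeEvent(
                    channel_id=leaf_ids[j],
                    t_nucleation=time_index[i_n],
                    T_nucleation=theta,
                    t_thaw=t_thaw,
                )
            )

    canopy = air - 0.4 * dep_sum / max(n_leaves, 1)
    values = np.vstack([leaf_values, air[None, :], canopy[None, :], soil[None, :]]).T
    values = values + rng.normal(0.0, config.noise_sd_c, size=values.shape)

    table = SensorTable(
        time=time_index,
        values=values,
        meta=meta,
        nominal_interval_s=dt,
    )
    truth = GroundTruth(
        events=events,
        night_frost_flags=frost_flags,
        snow_flags=snow_flags,
        leaf_channel_ids=leaf_ids,
    )
    return table, truth


def simulate_lt50_assay(
    params: BoltzmannParams,
    temps: Sequence[float],
    leaves_per_temp: int = 10,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic frost-damage assay: Fv/Fm on the Boltzmann curve plus
    Gaussian noise, clipped to the physical range [0, 0.9]."""
    if leaves_per_temp < 4:
        raise ParameterError("leaves_per_temp must be >= 4 (resampling draws 4)")
    rng = np.random.default_rng(seed)
    rows = []
    for j, temp in enumerate(temps):
        mu = boltzmann(temp, params)
        for i in range(leaves_per_temp):
            y = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "leaf_id": f"T{j:02d}_L{i:02d}",
                    "treatment_temp_c": float(temp),
                    "fvfm": float(np.clip(y, 0.0, 0.9)),
                }
            )
    return pd.DataFrame(rows)


def _truncated_share(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Truncated-normal CA share in (0, 1]."""
    if sd == 0:
        return mean
    for _ in range(1000):
        s = rng.normal(mean, sd)
        if 0 < s <= 1:
            return s
    raise RuntimeError("share rejection failed")  # pragma: no cover


def simulate_cell_outlines(
    n_cells: int,
    tissue: str = "palisade",
    share_mean: float = 0.54,
    share_sd: float = 0.15,
    seed: int = 0,
) -> tuple[list[CellOutline], list[CellOutline]]:
    """Baseline (+20 degC) and frozen outline per cell.

    Palisade cells are elongated rectangles (~20 x 90 um, random
    orientation) that shrink in width only, so the frozen area share
    equals the width share and the length is preserved — the
    diameter-biased response seen under the microscope.  Spongy cells
    are irregular star-shaped 8-14-gons shrinking isotropically.  Frozen
    shares are truncated-normal draws in (0, 1].
    """
    if not 0 < share_mean <= 1:
        raise ParameterError("share_mean must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    baselines: list[CellOutline] = []
    frozens: list[CellOutline] = []
    for i in range(n_cells):
        cid = f"{tissue[:3]}_{i:03d}"
        share = _truncated_share(rng, share_mean, share_sd)
        temp = rng.uniform(-8.0, -3.5)
        angle = rng.uniform(0, np.pi)
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        if tissue == "palisade":
            length = rng.uniform(80.0, 100.0)
            width = rng.uniform(18.0, 22.0)
            base_pts = np.array(
                [[-length / 2, -width / 2], [length / 2, -width / 2],
                 [length / 2, width / 2], [-length / 2, width / 2]]
            )
            frozen_pts = base_pts * np.array([1.0, share])  # width-only shrinkage
        elif tissue == "spongy":
            n_vert = int(rng.integers(8, 15))
            # evenly spaced angles with bounded jitter keep the star-shaped
            # polygon simple (no angular gap can exceed pi)
            ang = 2 * np.pi * (np.arange(n_vert) + rng.uniform(-0.3, 0.3, n_vert)) / n_vert
            radius = rng.uniform(15.0, 25.0) * rng.uniform(0.7, 1.3, n_vert)
            base_pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])
            frozen_pts = base_pts * np.sqrt(share)  # isotropic shrinkage
        else:
            raise ParameterError(f"unknown tissue {tissue!r}")
        base_pts = base_pts @ rot.T
        frozen_pts = frozen_pts @ rot.T
        baselines.append(CellOutline(cid, tissue, 20.0, "baseline", tuple(map(tuple, base_pts))))
        frozens.append(CellOutline(cid, tissue, temp, "frozen", tuple(map(tuple, frozen_pts))))
    return baselines, frozens


@dataclass(frozen=True)
class TrueNucleationFrame:
    """Ground truth for one injected IR freezing event."""

    region_id: int
    frame_index: int
    time_s: float


def simulate_idta_stack(
    n_regions: int,
    frames: int,
    nucleation_frames: Sequence[int],
    seed: int = 0,
    fps: float = 15.0,
    region_size: int = 12,
    jump: float = 1.5,
    spread_frames: int = 5,
    noise_sd: float = 0.02,
) -> tuple[FrameStack, np.ndarray, list[TrueNucleationFrame]]:
    """Synthetic IR stack: cooling leaf regions, one freezing event each.

    Each region cools linearly from +2 to −14 intensity units across the
    stack.  At its nucleation frame, ~50% of its pixels jump by
    ``jump`` units (the brindled pattern); the remaining pixels light up
    over the next ``spread_frames`` frames (homogeneous coverage); the
    warm excess then decays.  No second event occurs, however far
    cooling continues.
    """
    if len(nucleation_frames) != n_regions:
        raise ParameterError("one nucleation frame per region required")
    for f in nucleation_frames:
        if not 1 <= f < frames - spread_frames:
            raise ParameterError(f"nucleation frame {f} outside usable stack range")
    rng = np.random.default_rng(seed)

    gap = 4
    height = region_size + 2 * gap
    width = n_regions * (region_size + gap) + gap
    masks = np.zeros((height, width), dtype=np.uint16)
    for r in range(n_regions):
        c0 = gap + r * (region_size + gap)
        masks[gap : gap + region_size, c0 : c0 + region_size] = r + 1

    cool = np.linspace(2.0, -14.0, frames)
    stack = np.tile(cool[:, None, None], (1, height, width))

    truth = []
    tau_frames = 10.0
    for r in range(n_regions):
        f0 = int(nucleation_frames[r])
        mask = masks == r + 1
        pix = np.argwhere(mask)
        order = rng.permutation(len(pix))
        n_first = len(pix) // 2
        # onset frame per pixel: half at f0, the rest spread over the next frames
        onsets = np.empty(len(pix), dtype=int)
        onsets[order[:n_first]] = f0
        rest = order[n_first:]
        onsets[rest] = f0 + 1 + (np.arange(len(rest)) * spread_frames) // max(len(rest), 1)
        for (row, col), onset in zip(pix, onsets):
            t = np.arange(onset, frames)
            stack[t, row, col] += jump * np.exp(-(t - onset) / tau_frames)
        truth.append(TrueNucleationFrame(region_id=r + 1, frame_index=f0, time_s=f0 / fps))

    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    frame_stack = FrameStack(
        frames=stack,
        timestamps=np.arange(frames) / fps,
        region_masks=masks,
    )
    return frame_stack, masks, truth
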