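"""Infrared differential thermal analysis (IDTA) of image stacks.

An infrared camera watches leaves during controlled freezing.  The
latent heat of the advancing ice front warms frozen tissue relative to
the previous frame, so subtracting each frame from its predecessor
turns the front into a bright transient: per leaf region, the first
frame on which a sufficient fraction of pixels brightens marks ice
nucleation, and the cumulative set of pixels that have brightened maps
the front's spread (brindled at first, then homogeneous coverage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cryoleaf.errors import DataError, ParameterError


@dataclass
class FrameStack:
    """IR frame stack plus per-frame timestamps and leaf-region labels.

    frames
        Array ``(n_frames, height, width)``, intensity or temperature units.
    timestamps
        Strictly increasing per-frame instants (seconds, float).
    region_masks
        Integer label image ``(height, width)``; 0 = background, k > 0 = leaf k.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    region_masks: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.region_masks = np.asarray(self.region_masks)
        if self.frames.ndim != 3:
            raise DataError("frames must be (time, height, width)")
        if len(self.timestamps) != self.frames.shape[0]:
            raise DataError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.region_masks.shape != self.frames.shape[1:]:
            raise DataError("mask shape must match frame shape")

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.region_masks)
        return [int(r) for r in ids if r != 0]


@dataclass(frozen=True)
class NucleationEvent:
    """One detected freezing event in one leaf region."""

    region_id: int
    frame_index: int
    time: float
    peak_signal: float
    centroid: tuple[float, float]


def difference_stack(stack: FrameStack, lag_frames: int = 1) -> np.ndarray:
    """Frame-subtraction stack ``D_t = F_t − F_{t−lag}``.

    Output has ``n_frames − lag`` slices; slice ``i`` corresponds to
    original frame ``i + lag``.  Background pixels are NaN.
    """
    if lag_frames < 1:
        raise ParameterError("lag_frames must be >= 1")
    if lag_frames >= stack.frames.shape[0]:
        raise ParameterError("lag_frames must be smaller than the number of frames")
    d = stack.frames[lag_frames:] - stack.frames[:-lag_frames]
    d[:, stack.region_masks == 0] = np.nan
    return d


def detect_region_events(
    stack: FrameStack,
    threshold: float,
    min_fraction: float = 0.05,
    refractory_frames: int = 15,
    lag_frames: int = 1,
) -> list[NucleationEvent]:
    """Per-region nucleation events from the difference stack.

    A frame is flagged for a region when more than ``min_fraction`` of
    its pixels brightened by at least ``threshold`` since the lagged
    frame.  Runs of flagged frames within ``refractory_frames`` merge
    into one event anchored at the first flagged frame, so the brindled
    onset and the homogeneous spread count once.  Events are returned
    sorted by time.
    """
    if not stack.region_ids:
        raise DataError("region mask labels no regions")
    d = difference_stack(stack, lag_frames)
    events: list[NucleationEvent] = []
    for rid in stack.region_ids:
        mask = stack.region_masks == rid
        n_pix = int(mask.sum())
        region_d = d[:, mask]  # (n_diff_frames, n_pix)
        with np.errstate(invalid="ignore"):
            hot = region_d >= threshold
        frac = hot.sum(axis=1) / n_pix
        flagged = np.flatnonzero(frac > min_fraction)
        for run in _runs(flagged, refractory_frames):
            i0 = int(run[0])
            frame_index = i0 + lag_frames
            hot0 = np.zeros_like(mask, dtype=bool)
            hot0[mask] = hot[i0]
            rr, cc = np.nonzero(hot0)
            centroid = (float(rr.mean()), float(cc.mean())) if len(rr) else (np.nan, np.nan)
            events.append(
                NucleationEvent(
                    region_id=rid,
                    frame_index=frame_index,
                    time=float(stack.timestamps[frame_index]),
                    peak_signal=float(np.nanmax(region_d[run])),
                    centroid=centroid,
                )
            )
    return sorted(events, key=lambda e: e.time)


def _runs(indices: np.ndarray, max_gap: int) -> list[np.ndarray]:
    if len(indices) == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > max_gap) + 1
    return np.split(indices, breaks)


def coverage_curve(
    stack: FrameStack,
    event: NucleationEvent,
    threshold: float,
    lag_frames: int = 1,
) -> np.ndarray:
    """Cumulative ice-front coverage of a region after an event.

    For each frame, the fraction of region pixels that have *ever*
    brightened by ``threshold`` since the event — 0 before the event,
    non-decreasing afterwards, approaching 1 as the brindled pattern
    fills in.  Returned per original frame index.
    """
    mask = stack.region_masks == event.region_id
    if not mask.any():
        raise DataError(f"region {event.region_id} not present in mask")
    d = difference_stack(stack, lag_frames)
    n_frames = stack.frames.shape[0]
    n_pix = int(mask.sum())
    covered = np.zeros(n_pix, dtype=bool)
    curve = np.zeros(n_frames, dtype=float)
    for t in range(event.frame_index, n_frames):
        with np.errstate(invalid="ignore"):
            covered |= d[t - lag_frames, mask] >= threshold
        curve[t] = covered.sum() / n_pix
    return curve


def events_to_frame(events: list[NucleationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": e.region_id,
                "frame_index": e.frame_index,
                "time_s": e.time,
                "peak_signal": e.peak_signal,
                "centroid_row": e.centroid[0],
                "centroid_col": e.centroid[1],
            }
            for e in events
        ]
    )


def read_stack(stack_path, mask_path, timestamps_path) -> FrameStack:
    """Read a multi-frame TIFF stack, a labeled mask TIFF and a
    frame-timestamp CSV (column ``time_s``)."""
    import tifffile

    frames = tifffile.imread(stack_path)
    masks = tifffile.imread(mask_path)
    ts = pd.read_csv(timestamps_path)["time_s"].to_numpy(dtype=float)
    return FrameStack(frames=frames, timestamps=ts, region_masks=masks)


def write_stack(stack: FrameStack, stack_path, mask_path, timestamps_path) -> None:
    import tifffile

    tifffile.imwrite(stack_path, stack.frames.astype(np.float32))
    tifffile.imwrite(mask_path, stack.region_masks.astype(np.uint16))
    pd.DataFrame({"time_s": stack.timestamps}).to_csv(timestamps_path, index=False)
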