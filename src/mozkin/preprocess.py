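"""Masking, segmentation, length filtering and smoothing of raw trajectories.

Two mask profiles mirror the two analysis tracks:

* ``standard`` — drops frames closer than 6 cm to the upwind screen (the
  "bouncing" zone, where wall interaction contaminates free flight); no
  length filter, no smoothing.
* ``saccade`` — drops frames closer than 6 cm to any wall or 20 cm to the
  upwind screen, removes surviving runs shorter than 30 frames (0.5 s), and
  smooths the remainder with a 6-frame (0.1 s) moving average.

Frames are first split into contiguous runs at recording gaps (frame-index
steps > 1); masking then splits runs further.  Segments are maximal
contiguous surviving runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import ArenaConfig, Trajectory

logger = logging.getLogger(__name__)

PROFILES = ("standard", "saccade")


@dataclass
class MaskedTrajectory:
    """Contiguous frame runs of one trial surviving a named mask profile."""

    trial_id: str
    group: str
    profile: str
    segments: list[pd.DataFrame]

    @property
    def n_frames(self) -> int:
        return sum(len(s) for s in self.segments)

    def total_time_s(self, config: ArenaConfig) -> float:
        """Summed duration of all segments (frame count / frame rate)."""
        return self.n_frames / config.frame_rate_hz


def screen_distance(x_cm: np.ndarray, config: ArenaConfig) -> np.ndarray:
    """Distance to the upwind screen along the wind axis."""
    return config.arena_length_cm - np.asarray(x_cm, dtype=float)


def wall_distance(frames: pd.DataFrame, config: ArenaConfig) -> np.ndarray:
    """Distance to the nearest arena face (all six, including the screen)."""
    x = frames["x_cm"].to_numpy(dtype=float)
    y = frames["y_cm"].to_numpy(dtype=float)
    z = frames["z_cm"].to_numpy(dtype=float)
    return np.minimum.reduce([
        x, config.arena_length_cm - x,
        y, config.arena_height_cm - y,
        z, config.arena_width_cm - z,
    ])


def mask_predicate(frames: pd.DataFrame, profile: str, config: ArenaConfig) -> np.ndarray:
    """Boolean keep-mask for a frame table under the given profile."""
    if profile not in PROFILES:
        raise ValueError(f"unknown mask profile {profile!r}")
    if profile == "standard":
        return screen_distance(frames["x_cm"].to_numpy(), config) >= config.upwind_mask_cm
    keep = wall_distance(frames, config) >= config.wall_mask_cm
    keep &= screen_distance(frames["x_cm"].to_numpy(), config) >= config.saccade_upwind_mask_cm
    return keep


def split_contiguous(frames: pd.DataFrame) -> list[pd.DataFrame]:
    """Split a frame table into runs of consecutive frame indices."""
    if len(frames) == 0:
        return []
    idx = frames["frame"].to_numpy()
    breaks = np.flatnonzero(np.diff(idx) != 1) + 1
    bounds = [0, *breaks.tolist(), len(frames)]
    return [frames.iloc[lo:hi].reset_index(drop=True)
            for lo, hi in zip(bounds[:-1], bounds[1:])]


def apply_mask(traj: Trajectory, profile: str, config: ArenaConfig) -> MaskedTrajectory:
    """Apply a mask profile, returning maximal contiguous surviving runs.

    Under the ``saccade`` profile, runs shorter than
    ``config.min_segment_frames`` are removed after masking.  An empty
    result is valid.  Smoothing is *not* applied here; see
    :func:`preprocess_saccade` for the full saccade-track pipeline.
    """
    keep = mask_predicate(traj.frames, profile, config)
    surviving = traj.frames.loc[keep]
    segments = split_contiguous(surviving)
    if profile == "saccade":
        segments = [s for s in segments if len(s) >= config.min_segment_frames]
    return MaskedTrajectory(trial_id=traj.trial_id, group=traj.group,
                            profile=profile, segments=segments)


def smooth(seg: pd.DataFrame, config: ArenaConfig) -> pd.DataFrame:
    """Moving-average smoothing of the x/y/z columns of one segment.

    The window is ``config.smooth_window_frames`` (default 6, i.e. 0.1 s at
    60 fps), centred; with an even window the stencil at frame *i* is
    i-3 ... i+2.  Edge frames average over the truncated window.  Frame
    indices and timestamps are unchanged.  Segments shorter than the window
    are returned unchanged with a warning.
    """
    w = config.smooth_window_frames
    n = len(seg)
    if n < w:
        logger.warning("segment of %d frames shorter than smoothing window %d; returned unchanged",
                       n, w)
        return seg.copy()
    out = seg.copy()
    back = w // 2          # frames i-back ... i+fwd inclusive
    fwd = w - back - 1
    pos = seg[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)
    csum = np.zeros((n + 1, 3))
    np.cumsum(pos, axis=0, out=csum[1:])
    i = np.arange(n)
    lo = np.maximum(i - back, 0)
    hi = np.minimum(i + fwd, n - 1) + 1
    sm = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    out[["x_cm", "y_cm", "z_cm"]] = sm
    return out


def preprocess_saccade(traj: Trajectory, config: ArenaConfig) -> tuple[MaskedTrajectory, list[pd.DataFrame]]:
    """Full saccade-track preprocessing: mask, length-filter, smooth.

    Returns the masked trajectory (raw segments) and the parallel list of
    smoothed segments; the two lists are index-aligned so kinematics can be
    computed on either representation.
    """
    masked = apply_mask(traj, "saccade", config)
    smoothed = [smooth(s, config) for s in masked.segments]
    return masked, smoothed
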