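"""Per-frame kinematics: speed, angular velocity, tortuosity, saccades.

Angular velocity is defined from central-difference velocity vectors:
``v_i = (p_{i+1} - p_{i-1}) * fps / 2`` and the angular velocity at frame
*i* is the angle (degrees) between ``v_i`` and ``v_{i+1}`` multiplied by
the frame rate.  It is unsigned; a planar variant uses the velocity
projected onto the x–y (vertical) plane.  Frames where the quantity is
undefined (segment ends, zero-length velocity) are NaN and flagged, never
silently zero.

A saccade is a maximal run of consecutive frames whose angular velocity
strictly exceeds the 2000 deg/s threshold; its centre is the frame of the
within-bout maximum (earliest on ties).  Tortuosity of a window is the
summed 3-D step length divided by the chord between its endpoints, >= 1
for any valid window; turn consistency is the mean tortuosity over the
60 frames (1 s) following each saccade centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import ArenaConfig

logger = logging.getLogger(__name__)

#: chord lengths below this (cm) make tortuosity undefined
DEGENERATE_CHORD_CM = 1e-9


@dataclass
class KinematicSeries:
    """Per-frame kinematic quantities aligned to a segment's frames.

    All arrays have the segment's length; undefined entries are NaN with
    ``defined`` False.
    """

    speed_cm_s: np.ndarray
    ang_vel_3d_deg_s: np.ndarray
    ang_vel_xy_deg_s: np.ndarray
    defined: np.ndarray

    def variant(self, which: str) -> np.ndarray:
        if which == "3d":
            return self.ang_vel_3d_deg_s
        if which == "xy":
            return self.ang_vel_xy_deg_s
        raise ValueError(f"unknown angular-velocity variant {which!r}")


@dataclass(frozen=True)
class SaccadeEvent:
    """One supra-threshold angular-velocity bout.

    Frame fields are positional indices into the segment the event was
    detected in; ``centre_frame_index`` is the segment's global frame index
    at the centre, for reporting.
    """

    bout_start: int
    bout_end: int          # inclusive
    centre: int
    peak_deg_s: float
    centre_frame_index: int = -1


def _pairwise_angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle in degrees between row vectors of a and b (NaN where degenerate)."""
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(denom > 0, (a * b).sum(axis=1) / np.where(denom > 0, denom, 1.0), np.nan)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def angular_velocity(seg: pd.DataFrame, config: ArenaConfig) -> KinematicSeries:
    """Speed and unsigned angular velocity (3-D and x–y planar) of a segment.

    Requires at least 3 frames.  Speed is defined at frames 1..n-2 and
    angular velocity at frames 1..n-3; the rest are NaN/flagged.
    """
    n = len(seg)
    if n < 3:
        raise ValueError(f"segment too short for kinematics: {n} frames (need >= 3)")
    p = seg[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)
    fps = config.frame_rate_hz
    speed = np.full(n, np.nan)
    av3 = np.full(n, np.nan)
    avxy = np.full(n, np.nan)
    v = (p[2:] - p[:-2]) * (fps / 2.0)          # velocity at frames 1..n-2
    speed[1:n - 1] = np.linalg.norm(v, axis=1)
    if len(v) >= 2:
        ang3 = _pairwise_angle_deg(v[:-1], v[1:]) * fps
        av3[1:n - 2] = ang3
        vxy = v.copy()
        vxy[:, 2] = 0.0                          # project onto x–y plane
        angxy = _pairwise_angle_deg(vxy[:-1], vxy[1:]) * fps
        avxy[1:n - 2] = angxy
    defined = ~np.isnan(av3)
    if np.any(np.isnan(av3[1:n - 2])):
        logger.debug("angular velocity undefined at %d interior frames (zero-length velocity)",
                     int(np.isnan(av3[1:n - 2]).sum()))
    return KinematicSeries(speed_cm_s=speed, ang_vel_3d_deg_s=av3,
                           ang_vel_xy_deg_s=avxy, defined=defined)


def tortuosity(seg: pd.DataFrame, i_start: int, i_end: int) -> float:
    """Path length over chord length between two frames of a segment.

    ``i_start``/``i_end`` are positional indices; returns NaN for a
    degenerate chord (endpoints closer than 1e-9 cm).
    """
    n = len(seg)
    if not (0 <= i_start < i_end < n):
        raise ValueError(f"invalid window [{i_start}, {i_end}] for segment of {n} frames")
    p = seg[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)[i_start:i_end + 1]
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    chord = np.linalg.norm(p[-1] - p[0])
    if chord < DEGENERATE_CHORD_CM:
        return float("nan")
    return float(steps.sum() / chord)


def detect_saccades(kin: KinematicSeries, config: ArenaConfig) -> list[SaccadeEvent]:
    """Find maximal supra-threshold angular-velocity bouts.

    Thresholding is strict (> 2000 deg/s by default) on the configured
    variant; NaN frames never exceed the threshold, so bouts cannot span
    undefined frames.  Single-frame bouts are allowed; bouts separated by
    at least one sub-threshold frame are distinct events.
    """
    av = kin.variant(config.saccade_angvel_variant)
    with np.errstate(invalid="ignore"):
        above = av > config.saccade_threshold_deg_s
    events: list[SaccadeEvent] = []
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return events
    run_breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, run_breaks):
        start, end = int(run[0]), int(run[-1])
        centre = start + int(np.argmax(av[start:end + 1]))   # argmax -> earliest tie
        events.append(SaccadeEvent(bout_start=start, bout_end=end, centre=centre,
                                   peak_deg_s=float(av[centre])))
    return events


def saccade_frequency(events: list[SaccadeEvent], total_s: float) -> float:
    """Saccades per second of analysed flight time."""
    if total_s <= 0:
        raise ValueError(f"total analysed time must be > 0, got {total_s}")
    return len(events) / total_s


def post_saccade_tortuosities(seg: pd.DataFrame, events: list[SaccadeEvent],
                              config: ArenaConfig) -> list[float]:
    """Tortuosity over the post-saccade window of each event.

    The window spans [centre, centre + post_saccade_window_frames],
    truncated at the segment end; events with fewer than 2 remaining
    frames are skipped.
    """
    vals: list[float] = []
    n = len(seg)
    for ev in events:
        end = min(ev.centre + config.post_saccade_window_frames, n - 1)
        if end - ev.centre < 1:
            continue
        vals.append(tortuosity(seg, ev.centre, end))
    return vals


def turn_consistency(seg: pd.DataFrame, events: list[SaccadeEvent],
                     config: ArenaConfig) -> float:
    """Mean post-saccade tortuosity over a segment's events (NaN if none)."""
    if not events:
        raise ValueError("turn_consistency requires at least one saccade event")
    vals = [v for v in post_saccade_tortuosities(seg, events, config) if not np.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))
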