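"""Per-trial flight variables and responder scoring.

Each responding trial is reduced to the five summary variables used for
group comparison and PCA:

* ``flight_duration_s`` — time spent in the filmed volume excluding
  "bouncing" frames (within 6 cm of the upwind screen);
* ``prop_bouncing`` — bouncing frames over all filmed-volume frames;
* ``prop_voi`` — frames inside the 14 cm volume-of-interest cylinder over
  the standard-profile (non-bouncing) filmed-volume frames;
* ``saccade_freq_hz`` — detected saccades per second of saccade-profile
  flight time;
* ``turn_consistency`` — mean tortuosity over the 1 s after each saccade
  centre.

The denominator convention for the two proportions ("total number of
frames" = frames inside the filmed volume, i.e. the filmed data) is a
documented choice; the VOI cylinder's axis runs along the wind axis
through the cross-section centre and spans the filmed volume.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import ArenaConfig, METRICS_COLUMNS, Trajectory
from .kinematics import (SaccadeEvent, angular_velocity, detect_saccades,
                         post_saccade_tortuosities)
from .preprocess import apply_mask, screen_distance, smooth

logger = logging.getLogger(__name__)


@dataclass
class FlightMetrics:
    """The five per-trial flight variables plus the responder flag.

    Non-responders carry no flight variables (all NaN).
    """

    trial_id: str
    group: str
    responded: bool
    flight_duration_s: float = float("nan")
    prop_bouncing: float = float("nan")
    prop_voi: float = float("nan")
    saccade_freq_hz: float = float("nan")
    turn_consistency: float = float("nan")

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


def score_response(traj: Trajectory | None, config: ArenaConfig) -> bool:
    """True iff the animal entered the filmed volume within the response window.

    ``traj`` may be None (no recorded entry at all -> non-responder).
    Release time is t = 0; entry at exactly the window boundary counts.
    """
    if traj is None or len(traj) == 0:
        return False
    x = traj.frames["x_cm"].to_numpy(dtype=float)
    t = traj.frames["t_s"].to_numpy(dtype=float)
    inside = x >= config.filmed_volume_min_x_cm
    return bool(np.any(inside & (t <= config.response_window_s)))


def _filmed_mask(traj: Trajectory, config: ArenaConfig) -> np.ndarray:
    return traj.frames["x_cm"].to_numpy(dtype=float) >= config.filmed_volume_min_x_cm


def _bounce_mask(traj: Trajectory, config: ArenaConfig) -> np.ndarray:
    return screen_distance(traj.frames["x_cm"].to_numpy(), config) < config.upwind_mask_cm


def bouncing_proportion(traj: Trajectory, config: ArenaConfig) -> float:
    """Fraction of filmed-volume frames within 6 cm of the upwind screen."""
    if len(traj) == 0:
        raise ValueError(f"trial {traj.trial_id!r}: empty trajectory")
    filmed = _filmed_mask(traj, config)
    n = int(filmed.sum())
    if n == 0:
        raise ValueError(f"trial {traj.trial_id!r}: no filmed-volume frames")
    return float((_bounce_mask(traj, config) & filmed).sum() / n)


def flight_duration(traj: Trajectory, config: ArenaConfig) -> float:
    """Seconds spent in the filmed volume excluding bouncing frames."""
    filmed = _filmed_mask(traj, config)
    active = filmed & ~_bounce_mask(traj, config)
    return float(active.sum() / config.frame_rate_hz)


def voi_proportion(traj: Trajectory, config: ArenaConfig) -> float:
    """Fraction of standard-profile filmed frames inside the VOI cylinder.

    The cylinder (diameter 14 cm) is centred in the y–z cross-section with
    its axis along the wind axis, spanning the filmed volume.  Frames are
    inside iff their radial distance from the axis is < 7 cm.  Returns NaN
    if no standard-profile filmed frame exists.
    """
    filmed = _filmed_mask(traj, config)
    standard = filmed & ~_bounce_mask(traj, config)
    n = int(standard.sum())
    if n == 0:
        return float("nan")
    y = traj.frames["y_cm"].to_numpy(dtype=float)
    z = traj.frames["z_cm"].to_numpy(dtype=float)
    cy = config.arena_height_cm / 2.0
    cz = config.arena_width_cm / 2.0
    inside = (y - cy) ** 2 + (z - cz) ** 2 < config.voi_radius_cm ** 2
    return float((inside & standard).sum() / n)


def saccade_summary(traj: Trajectory, config: ArenaConfig) -> tuple[float, float, list[SaccadeEvent]]:
    """Saccade frequency and turn consistency from the saccade-profile track.

    Applies the saccade mask (6 cm walls, 20 cm screen), drops segments
    shorter than 30 frames, detects saccades on each segment's angular
    velocity (smoothed positions first iff ``config.detect_on_smoothed``)
    and evaluates post-saccade tortuosity on the smoothed positions.
    Returns (saccade_freq_hz, turn_consistency, events); frequencies are
    NaN when no analysable segment exists, turn consistency NaN when no
    event yields a valid window.
    """
    masked = apply_mask(traj, "saccade", config)
    total_s = masked.total_time_s(config)
    if total_s <= 0:
        return float("nan"), float("nan"), []
    all_events: list[SaccadeEvent] = []
    tort_vals: list[float] = []
    for seg in masked.segments:
        sm = smooth(seg, config)
        detect_seg = sm if config.detect_on_smoothed else seg
        if len(detect_seg) < 4:
            continue
        kin = angular_velocity(detect_seg, config)
        events = detect_saccades(kin, config)
        frame_idx = seg["frame"].to_numpy()
        events = [dataclasses.replace(ev, centre_frame_index=int(frame_idx[ev.centre]))
                  for ev in events]
        all_events.extend(events)
        tort_vals.extend(v for v in post_saccade_tortuosities(sm, events, config)
                         if not math.isnan(v))
    freq = len(all_events) / total_s
    tc = float(np.mean(tort_vals)) if tort_vals else float("nan")
    return freq, tc, all_events


def summarize_trial(traj: Trajectory | None, config: ArenaConfig, *,
                    trial_id: str | None = None, group: str | None = None) -> FlightMetrics:
    """Reduce one trial to :class:`FlightMetrics`.

    Standard-profile frames feed duration/bouncing/VOI; the saccade profile
    feeds saccade frequency and turn consistency.  Non-responders (or a
    missing trajectory) yield a responded=False row with NaN variables.
    """
    responded = score_response(traj, config)
    if not responded:
        return FlightMetrics(trial_id=trial_id or (traj.trial_id if traj else "?"),
                             group=group or (traj.group if traj else "?"),
                             responded=False)
    assert traj is not None
    freq, tc, _ = saccade_summary(traj, config)
    return FlightMetrics(
        trial_id=traj.trial_id, group=traj.group, responded=True,
        flight_duration_s=flight_duration(traj, config),
        prop_bouncing=bouncing_proportion(traj, config),
        prop_voi=voi_proportion(traj, config),
        saccade_freq_hz=freq,
        turn_consistency=tc,
    )


def summarize_trials(trajs: list[Trajectory], config: ArenaConfig,
                     trial_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Metrics table for a set of trials.

    ``trial_table`` (columns ``trial_id``, ``group``) lists every released
    animal, including non-responders that produced no trajectory; if None,
    only trials with trajectories appear.
    """
    by_id = {t.trial_id: t for t in trajs}
    rows = []
    if trial_table is not None:
        for _, rec in trial_table.iterrows():
            traj = by_id.get(str(rec["trial_id"]))
            rows.append(summarize_trial(traj, config, trial_id=str(rec["trial_id"]),
                                        group=str(rec["group"])).as_row())
    else:
        for traj in trajs:
            rows.append(summarize_trial(traj, config).as_row())
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)
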