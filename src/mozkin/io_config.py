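"""Experiment configuration and delimited-text I/O.

The configuration (:class:`ArenaConfig`) is the single source of truth for
the wind-tunnel geometry and every analysis constant; all downstream stages
take it as an argument rather than hard-coding numbers.

Coordinate convention
---------------------
``x`` is the longitudinal (wind) axis, increasing toward the upwind screen,
so the screen sits at ``x = arena_length_cm``; ``y`` is vertical and ``z``
lateral.  The original tracking system's axis assignment is not recoverable,
so this convention is fixed here and stated prominently: the "vertical
plane" used for planar angular velocity is the x–y plane under it.
Positions are in centimetres, times in seconds, frame indices 0-based.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance (cm) for clamping positions marginally outside the arena
POSITION_TOL_CM = 1e-6
#: tolerance (s) on the uniform frame spacing of contiguous frames
TIME_TOL_S = 1e-6

TRAJECTORY_COLUMNS = ["trial_id", "group", "frame", "t_s", "x_cm", "y_cm", "z_cm"]
SPIKE_COLUMNS = ["sensillum_id", "neuron", "genotype", "compound", "log10_dose", "spike_time_s"]
METRICS_COLUMNS = [
    "trial_id", "group", "responded", "flight_duration_s", "prop_bouncing",
    "prop_voi", "saccade_freq_hz", "turn_consistency",
]


class ConfigError(ValueError):
    """Invalid or inconsistent configuration values."""


class TrajectoryParseError(ValueError):
    """Malformed trajectory/spike input; message names the offending line."""


class TrajectoryValidationError(ValueError):
    """Trajectory violates an arena/timing invariant; message names the trial."""


@dataclass(frozen=True)
class ArenaConfig:
    """Wind-tunnel geometry, camera timing and analysis constants.

    Defaults reproduce the study conditions: a 200 x 60 x 60 cm arena filmed
    at 60 frames/s over the 120 cm at the upwind end, 6 cm exclusion masks,
    a 2000 deg/s saccade threshold and a 14 cm volume-of-interest cylinder.
    """

    arena_length_cm: float = 200.0
    arena_width_cm: float = 60.0
    arena_height_cm: float = 60.0
    filmed_length_cm: float = 120.0
    frame_rate_hz: float = 60.0
    upwind_mask_cm: float = 6.0
    wall_mask_cm: float = 6.0
    saccade_upwind_mask_cm: float = 20.0
    min_segment_frames: int = 30
    smooth_window_frames: int = 6
    saccade_threshold_deg_s: float = 2000.0
    post_saccade_window_frames: int = 60
    voi_diameter_cm: float = 14.0
    response_window_s: float = 300.0
    # which angular-velocity variant feeds saccade thresholding ("3d" or "xy");
    # the 3-D variant is the default
    saccade_angvel_variant: str = "3d"
    # whether saccade thresholding uses angular velocity from smoothed positions;
    # the tracker computed angular velocity upstream of smoothing, so default False
    detect_on_smoothed: bool = False

    def __post_init__(self) -> None:
        for name in ("arena_length_cm", "arena_width_cm", "arena_height_cm",
                     "filmed_length_cm", "frame_rate_hz", "voi_diameter_cm",
                     "response_window_s", "saccade_threshold_deg_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.filmed_length_cm > self.arena_length_cm:
            raise ConfigError("filmed_length_cm exceeds arena_length_cm")
        if not (0 <= self.upwind_mask_cm < self.arena_length_cm):
            raise ConfigError("upwind_mask_cm out of range")
        if not (0 <= self.wall_mask_cm < min(self.arena_width_cm, self.arena_height_cm) / 2):
            raise ConfigError("wall_mask_cm out of range")
        if self.saccade_upwind_mask_cm < self.upwind_mask_cm:
            raise ConfigError("saccade_upwind_mask_cm must be >= upwind_mask_cm")
        if self.saccade_upwind_mask_cm >= self.arena_length_cm:
            raise ConfigError("saccade_upwind_mask_cm out of range")
        if self.min_segment_frames < 2:
            raise ConfigError("min_segment_frames must be >= 2")
        if self.smooth_window_frames < 1:
            raise ConfigError("smooth_window_frames must be >= 1")
        if self.post_saccade_window_frames < 1:
            raise ConfigError("post_saccade_window_frames must be >= 1")
        if self.saccade_angvel_variant not in ("3d", "xy"):
            raise ConfigError("saccade_angvel_variant must be '3d' or 'xy'")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def filmed_volume_min_x_cm(self) -> float:
        """Downwind edge of the filmed volume along the wind axis."""
        return self.arena_length_cm - self.filmed_length_cm

    @property
    def voi_radius_cm(self) -> float:
        return self.voi_diameter_cm / 2.0

    # -- flat key=value serialization -------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ArenaConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"line {lineno}: unknown configuration key {key!r}")
            if key in ("min_segment_frames", "smooth_window_frames", "post_saccade_window_frames"):
                kwargs[key] = int(value)
            elif key == "detect_on_smoothed":
                kwargs[key] = value.lower() in ("true", "1", "yes")
            elif key == "saccade_angvel_variant":
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class Trajectory:
    """One trial's time-ordered 3-D position series.

    ``frames`` has columns ``frame`` (0-based index), ``t_s``, ``x_cm``,
    ``y_cm``, ``z_cm`` sorted by frame index.
    """

    trial_id: str
    group: str
    frames: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) position array in cm, columns x, y, z."""
        return self.frames[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float)

    def validate(self, config: ArenaConfig) -> "Trajectory":
        """Check ordering, arena bounds (with clamping) and frame spacing.

        Marginal out-of-arena excursions within ``POSITION_TOL_CM`` are
        clamped in place; anything beyond raises
        :class:`TrajectoryValidationError`.
        """
        fr = self.frames
        idx = fr["frame"].to_numpy()
        t = fr["t_s"].to_numpy(dtype=float)
        if len(fr) == 0:
            raise TrajectoryValidationError(f"trial {self.trial_id!r}: empty trajectory")
        if np.any(np.diff(idx) <= 0):
            raise TrajectoryValidationError(
                f"trial {self.trial_id!r}: frame indices not strictly increasing")
        if np.any(np.diff(t) <= 0):
            raise TrajectoryValidationError(
                f"trial {self.trial_id!r}: timestamps not strictly increasing")
        bounds = {
            "x_cm": config.arena_length_cm,
            "y_cm": config.arena_height_cm,
            "z_cm": config.arena_width_cm,
        }
        for col, hi in bounds.items():
            v = fr[col].to_numpy(dtype=float)
            if np.any(v < -POSITION_TOL_CM) or np.any(v > hi + POSITION_TOL_CM):
                bad = v[(v < -POSITION_TOL_CM) | (v > hi + POSITION_TOL_CM)][0]
                raise TrajectoryValidationError(
                    f"trial {self.trial_id!r}: {col} = {bad} outside arena [0, {hi}]")
            fr[col] = np.clip(v, 0.0, hi)
        # contiguous frames (index step 1) must be uniformly spaced at 1/fps
        step = np.diff(idx)
        dt = np.diff(t)
        contiguous = step == 1
        if np.any(np.abs(dt[contiguous] - config.dt_s) > TIME_TOL_S):
            raise TrajectoryValidationError(
                f"trial {self.trial_id!r}: contiguous frame spacing deviates from "
                f"1/{config.frame_rate_hz} s by more than {TIME_TOL_S} s")
        return self


@dataclass
class SpikeRecord:
    """Spike times for one (sensillum, neuron, compound, dose) presentation.

    Times are seconds relative to stimulus onset at 0; the record is expected
    to cover the spontaneous window [-0.5, 0) and the stimulation window
    [0, stim_duration_s).
    """

    sensillum_id: str
    neuron: str
    genotype: str
    compound: str
    log10_dose: float
    spike_times_s: np.ndarray
    stim_duration_s: float = 0.5

    def __post_init__(self) -> None:
        if self.neuron not in ("A", "B"):
            raise TrajectoryParseError(
                f"sensillum {self.sensillum_id!r}: neuron must be 'A' or 'B', got {self.neuron!r}")
        if self.stim_duration_s <= 0:
            raise ConfigError("stim_duration_s must be > 0")
        self.spike_times_s = np.sort(np.asarray(self.spike_times_s, dtype=float))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_trajectories(path: str | Path, config: ArenaConfig) -> list[Trajectory]:
    """Read a trajectory CSV into one validated :class:`Trajectory` per trial.

    The file must have header ``trial_id,group,frame,t_s,x_cm,y_cm,z_cm``.
    Frames are sorted per trial regardless of input row order.
    """
    try:
        df = pd.read_csv(path, dtype={"trial_id": str, "group": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrajectoryParseError(f"{path}: {exc}") from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")
    for col in ("frame", "t_s", "x_cm", "y_cm", "z_cm"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            # +2: header line and 1-based numbering
            line = int(numeric.index[numeric.isna()][0]) + 2
            raise TrajectoryParseError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = numeric
    out: list[Trajectory] = []
    for trial_id, sub in df.groupby("trial_id", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise TrajectoryParseError(
                f"{path}: trial {trial_id!r} has inconsistent group labels {sorted(groups)}")
        frames = (sub[["frame", "t_s", "x_cm", "y_cm", "z_cm"]]
                  .astype({"frame": int})
                  .sort_values("frame")
                  .reset_index(drop=True))
        traj = Trajectory(trial_id=str(trial_id), group=str(groups[0]), frames=frames)
        out.append(traj.validate(config))
    return out


def write_trajectories(trajs: Iterable[Trajectory], path: str | Path) -> None:
    parts = []
    for tr in trajs:
        block = tr.frames.copy()
        block.insert(0, "group", tr.group)
        block.insert(0, "trial_id", tr.trial_id)
        parts.append(block)
    df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9f")


def read_spikes(path: str | Path) -> list[SpikeRecord]:
    """Read a spike CSV into one :class:`SpikeRecord` per presentation.

    One row per spike; a presentation with no spikes is represented by a row
    with blank ``spike_time_s``.  Records are grouped by
    (sensillum_id, neuron, genotype, compound, log10_dose) with sorted times.
    """
    df = pd.read_csv(path, dtype={"sensillum_id": str, "neuron": str,
                                  "genotype": str, "compound": str})
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")
    bad_neuron = ~df["neuron"].isin(["A", "B"])
    if bad_neuron.any():
        line = int(df.index[bad_neuron][0]) + 2
        raise TrajectoryParseError(
            f"{path}: line {line}: neuron must be 'A' or 'B', got {df.loc[bad_neuron, 'neuron'].iloc[0]!r}")
    return spike_records_from_table(df)


def spike_records_from_table(df: pd.DataFrame) -> list[SpikeRecord]:
    """Group a spike table (one row per spike) into :class:`SpikeRecord` objects."""
    df = df.copy()
    df["log10_dose"] = pd.to_numeric(df["log10_dose"])
    df["spike_time_s"] = pd.to_numeric(df["spike_time_s"], errors="coerce")
    records: list[SpikeRecord] = []
    keys = ["sensillum_id", "neuron", "genotype", "compound", "log10_dose"]
    for key, sub in df.groupby(keys, sort=True):
        times = sub["spike_time_s"].dropna().to_numpy(dtype=float)
        records.append(SpikeRecord(
            sensillum_id=str(key[0]), neuron=str(key[1]), genotype=str(key[2]),
            compound=str(key[3]), log10_dose=float(key[4]), spike_times_s=times))
    return records


def write_spikes(records: Iterable[SpikeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        if len(rec.spike_times_s) == 0:
            rows.append((rec.sensillum_id, rec.neuron, rec.genotype,
                         rec.compound, rec.log10_dose, ""))
        for t in rec.spike_times_s:
            rows.append((rec.sensillum_id, rec.neuron, rec.genotype,
                         rec.compound, rec.log10_dose, f"{t:.9f}"))
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, index=False)


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    """Write the per-trial flight metrics table with the standard schema."""
    missing = [c for c in METRICS_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing columns {missing}")
    metrics[METRICS_COLUMNS].to_csv(path, index=False, float_format="%.9f")


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"trial_id": str, "group": str})
    df["responded"] = df["responded"].astype(bool)
    return df
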