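import numpy as np
import pandas as pd
import pytest

from mozkin import ArenaConfig, Trajectory


@pytest.fixture(scope="session")
def config() -> ArenaConfig:
    return ArenaConfig()


def make_trajectory(positions: np.ndarray, trial_id: str = "t0", group: str = "g",
                    fps: float = 60.0, frame0: int = 0) -> Trajectory:
    """Trajectory from an (n, 3) position array with uniform frame spacing."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    frames = pd.DataFrame({
        "frame": np.arange(frame0, frame0 + n),
        "t_s": np.arange(frame0, frame0 + n) / fps,
        "x_cm": positions[:, 0],
        "y_cm": positions[:, 1],
        "z_cm": positions[:, 2],
    })
    return Trajectory(trial_id=trial_id, group=group, frames=frames)


def straight_path(n: int = 120, start=(90.0, 30.0, 30.0), step=(0.5, 0.0, 0.0)) -> np.ndarray:
    """Constant-velocity straight line inside the arena."""
    return np.asarray(start, dtype=float) + np.arange(n)[:, None] * np.asarray(step, dtype=float)


@pytest.fixture(scope="session")
def two_preset_metrics(config):
    """Metrics tables from 10 seeded teneral/mature simulator runs (n=30 each).

    Session-scoped: shared by the duration-ratio recovery and the group-
    ordering tests to avoid re-simulating.
    Returns a list of (seed, metrics DataFrame) pairs.
    """
    import mozkin as mk

    out = []
    for seed in range(10):
        frames = []
        for preset in ("teneral", "mature"):
            params = mk.flight_preset(preset, seed=seed * 2 + (preset == "mature"))
            traj, truth = mk.simulate_flights(params, config)
            trajs = mk.trajectories_from_table(traj, config)
            frames.append(mk.summarize_trials(trajs, config, truth[["trial_id", "group"]]))
        out.append((seed, pd.concat(frames, ignore_index=True)))
    return out


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
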