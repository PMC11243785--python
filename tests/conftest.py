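import numpy as np
import pandas as pd
import pytest

from herdtrack.io import Trajectory, WaterPoint, compute_features


def make_trajectory(
    xy: np.ndarray,
    animal_id: str = "cow",
    interval_min: float = 2.0,
    start: str = "2018-05-28T00:00:00",
) -> Trajectory:
    """Trajectory from an (n, 2) position array at a regular interval."""
    xy = np.asarray(xy, dtype=float)
    ts = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(xy)) * interval_min, unit="m")
    return Trajectory(
        animal_id=animal_id,
        fixes=pd.DataFrame({"timestamp": ts, "x": xy[:, 0], "y": xy[:, 1]}),
        nominal_interval=interval_min,
    )


def planted_movement_slice(seed: int, water=WaterPoint(0.0, 0.0)) -> pd.DataFrame:
    """Feature table of a three-regime movement slice (121 fixes, 120 steps).

    Steps 1-40 quasi-stationary (rate ~ GPS noise), steps 41-80 directed
    movement at ~50 m/min, steps 81-120 stationary again at the new
    location. True change points in the 120 analyzed records: 40 and 80.
    """
    rng = np.random.default_rng(seed)
    n = 121
    x = np.zeros(n)
    y = np.zeros(n)
    heading = rng.uniform(-np.pi, np.pi)
    for j in range(1, n):
        if 40 < j <= 80:
            step = max(rng.normal(50.0, 5.0), 0.0) * 2.0
            heading += rng.normal(0.0, 0.1)
        else:
            step = 0.0
        x[j] = x[j - 1] + step * np.sin(heading)
        y[j] = y[j - 1] + step * np.cos(heading)
    x += rng.normal(0.0, 2.0, n)
    y += rng.normal(0.0, 2.0, n)
    return compute_features(make_trajectory(np.column_stack([x, y])), water)


@pytest.fixture
def water():
    return WaterPoint(0.0, 0.0)


@pytest.fixture(scope="session")
def small_herd():
    """2 animals x 1 day herd, shared across tests (read-only)."""
    from herdtrack.simulate import SimulatorConfig, simulate_herd

    cfg = SimulatorConfig(n_animals=2, days=1.0, seed=7)
    fixes, truth = simulate_herd(cfg)
    return cfg, fixes, truth
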