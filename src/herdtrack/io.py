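"""Reading, validating, projecting and quality-filtering GPS fix tables.

A *fix* is one timestamped position for one animal. Tracks arrive as CSV
with columns ``{animal_id, timestamp, x, y}`` (projected meters) or
``{animal_id, timestamp, lon, lat}`` (WGS84 degrees, projected locally on
read). Three per-fix movement features drive the downstream analysis:

rate
    step distance divided by elapsed time, in m/min — the velocity proxy.
course
    compass bearing of the step, degrees clockwise from north in [0, 360).
d2w
    Euclidean distance from the fix to the pasture's single water source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6371008.8

FIX_COLUMNS = ("animal_id", "timestamp", "x", "y")
LONLAT_COLUMNS = ("animal_id", "timestamp", "lon", "lat")


class SchemaError(ValueError):
    """Input table does not have the required columns/types."""


class ValidationError(ValueError):
    """Input table violates a trajectory invariant (e.g. duplicate times)."""


@dataclass(frozen=True)
class WaterPoint:
    """Projected coordinates of the single water source."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("water point coordinates must be finite")


@dataclass
class Trajectory:
    """Time-ordered GPS fixes for one animal.

    ``fixes`` is a DataFrame with columns timestamp (datetime64), x, y;
    strictly increasing timestamps; length >= 2.
    """

    animal_id: str
    fixes: pd.DataFrame
    nominal_interval: float = 2.0  # minutes

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if len(self.fixes) < 2:
            raise ValidationError(
                f"animal {self.animal_id!r}: trajectory needs >= 2 fixes"
            )
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValidationError(
                f"animal {self.animal_id!r}: timestamps not strictly increasing"
            )
        xy = self.fixes[["x", "y"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise ValidationError(f"animal {self.animal_id!r}: non-finite positions")

    def __len__(self) -> int:
        return len(self.fixes)


def project_lonlat(lon, lat, ref_lon: float, ref_lat: float):
    """Project lon/lat degrees to local meters about a reference point.

    Equirectangular approximation: x = R cos(lat_ref) Δlon, y = R Δlat
    (angles in radians, R the mean earth radius). Position error is below
    0.1% across a pasture-scale (≤10 km) extent, which is far below GPS
    noise; no external projection database is needed.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) >= 89.0) or abs(ref_lat) >= 89.0:
        raise ValueError("latitudes must satisfy |lat| < 89 degrees")
    if np.any(np.abs(lon) > 360.0) or abs(ref_lon) > 360.0:
        raise ValueError("longitude out of range")
    x = EARTH_RADIUS_M * np.cos(np.radians(ref_lat)) * np.radians(lon - ref_lon)
    y = EARTH_RADIUS_M * np.radians(lat - ref_lat)
    return x, y


def read_fixes(
    path,
    lonlat: bool = False,
    reference: tuple[float, float] | None = None,
    nominal_interval: float = 2.0,
) -> list[Trajectory]:
    """Read a fix CSV into one time-sorted :class:`Trajectory` per animal.

    Parameters
    ----------
    path
        CSV with header; columns ``animal_id, timestamp, x, y`` or, with
        ``lonlat=True``, ``animal_id, timestamp, lon, lat``.
    lonlat
        Interpret positions as WGS84 degrees and project them locally.
    reference
        (lon, lat) of the projection origin; defaults to the data centroid.
    nominal_interval
        Intended fix spacing in minutes (used by QC expectations).
    """
    df = pd.read_csv(path)
    required = LONLAT_COLUMNS if lonlat else FIX_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"timestamps not parseable as ISO-8601: {exc}") from None

    if lonlat:
        if reference is None:
            reference = (float(df["lon"].mean()), float(df["lat"].mean()))
        x, y = project_lonlat(df["lon"], df["lat"], reference[0], reference[1])
        df = df.assign(x=x, y=y)

    dup = df.duplicated(subset=["animal_id", "timestamp"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        raise ValidationError(f"duplicate animal/timestamp at input rows {rows}")

    trajs = []
    for animal_id, group in df.groupby("animal_id", sort=True):
        group = group.sort_values("timestamp").reset_index(drop=True)
        trajs.append(
            Trajectory(
                animal_id=str(animal_id),
                fixes=group[["timestamp", "x", "y"]].copy(),
                nominal_interval=nominal_interval,
            )
        )
    return trajs


def qc_filter_animals(
    trajs: list[Trajectory],
    max_gap: float = 180.0,
    max_missing_frac: float = 0.1,
) -> tuple[list[Trajectory], list[tuple[str, str]]]:
    """Drop animals whose collars failed for long stretches.

    An animal is dropped if any inter-fix gap exceeds ``max_gap`` minutes,
    or if the overall fraction of missing fixes (expected count = time span
    / nominal interval + 1) exceeds ``max_missing_frac``. Returns
    ``(kept, dropped)`` where dropped entries are ``(animal_id, reason)``.
    Loosening either threshold never drops a previously kept animal.
    """
    kept: list[Trajectory] = []
    dropped: list[tuple[str, str]] = []
    for traj in trajs:
        ts = traj.fixes["timestamp"]
        gaps = ts.diff().dt.total_seconds().to_numpy()[1:] / 60.0
        span = (ts.iloc[-1] - ts.iloc[0]).total_seconds() / 60.0
        expected = span / traj.nominal_interval + 1.0
        missing_frac = max(0.0, 1.0 - len(traj) / expected)
        if gaps.size and np.max(gaps) > max_gap:
            dropped.append((traj.animal_id, "gap"))
        elif missing_frac > max_missing_frac:
            dropped.append((traj.animal_id, "missing"))
        else:
            kept.append(traj)
    return kept, dropped


def compute_features(
    traj: Trajectory, water: WaterPoint, utc_offset: int = 0
) -> pd.DataFrame:
    """Per-fix movement features for one animal.

    The first fix has no predecessor, so its rate and course are null; it
    still carries d2w and is excluded from windowed analysis downstream.
    A zero-length step has no meaningful heading: its course is carried
    forward from the previous defined course (back-filled at the start of
    a track, 0 for an entirely stationary track).

    ``utc_offset`` (hours) converts stored timestamps to local time for the
    hour-of-day column used in diurnal summaries.
    """
    df = traj.fixes
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    dt = df["timestamp"].diff().dt.total_seconds().to_numpy() / 60.0
    if np.any(dt[1:] <= 0):
        raise ValidationError(
            f"animal {traj.animal_id!r}: non-positive elapsed time between fixes"
        )
    dx = np.diff(x, prepend=np.nan)
    dy = np.diff(y, prepend=np.nan)
    dist = np.hypot(dx, dy)
    rate = dist / dt
    # bearing clockwise from north: atan2(east, north)
    course = np.degrees(np.arctan2(dx, dy)) % 360.0
    course[dist == 0.0] = np.nan
    course = (
        pd.Series(course).ffill().bfill().fillna(0.0).to_numpy()
    )
    course[0] = np.nan
    d2w = np.hypot(x - water.x, y - water.y)
    hour = ((df["timestamp"].dt.hour + utc_offset) % 24).to_numpy()
    return pd.DataFrame(
        {
            "animal_id": traj.animal_id,
            "timestamp": df["timestamp"].to_numpy(),
            "x": x,
            "y": y,
            "rate": rate,
            "course": course,
            "d2w": d2w,
            "hour": hour,
        }
    )


def compute_feature_table(
    trajs: list[Trajectory], water: WaterPoint, utc_offset: int = 0
) -> pd.DataFrame:
    """Feature rows for every animal, concatenated in animal order."""
    if not trajs:
        return pd.DataFrame(
            columns=["animal_id", "timestamp", "x", "y", "rate", "course", "d2w", "hour"]
        )
    return pd.concat(
        [compute_features(t, water, utc_offset) for t in trajs], ignore_index=True
    )


def write_fixes(trajs: list[Trajectory], path) -> None:
    """Write trajectories back to the canonical fix CSV (round-trip safe)."""
    frames = []
    for t in trajs:
        frame = t.fixes.copy()
        frame.insert(0, "animal_id", t.animal_id)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
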