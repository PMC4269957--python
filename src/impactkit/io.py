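"""Reading and writing the delimited-text formats used by the pipeline.

Marker tracks travel as CSV with columns ``frame,time_s,m1_x,m1_y,m2_x,m2_y``
(meters/seconds, header required, no missing frames); cohort tables as tidy
CSV ``animal_id,group,timepoint,measure,value``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import KinematicSeries, MarkerTrack

TRACK_COLUMNS = ["frame", "time_s", "m1_x", "m1_y", "m2_x", "m2_y"]
COHORT_COLUMNS = ["animal_id", "group", "timepoint", "measure", "value"]


def write_track(track: MarkerTrack, path: str | Path) -> None:
    """Write a marker track to CSV (units: meters / seconds)."""
    df = pd.DataFrame(
        {
            "frame": np.arange(track.n_frames),
            "time_s": track.time,
            "m1_x": track.marker1[:, 0],
            "m1_y": track.marker1[:, 1],
            "m2_x": track.marker2[:, 0],
            "m2_y": track.marker2[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_track(
    path: str | Path, animal_id: str | None = None, impact_index: int = 1
) -> MarkerTrack:
    """Read a marker track CSV; the frame rate is inferred from the time step."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track file {path} lacks required columns {missing}")
    frames = df["frame"].to_numpy()
    if not np.array_equal(frames, np.arange(len(df))):
        raise ValueError(f"track file {path} has missing or out-of-order frames")
    time = df["time_s"].to_numpy(dtype=float)
    dt = np.median(np.diff(time))
    return MarkerTrack(
        time=time,
        marker1=df[["m1_x", "m1_y"]].to_numpy(dtype=float),
        marker2=df[["m2_x", "m2_y"]].to_numpy(dtype=float),
        frame_rate=1.0 / dt,
        animal_id=animal_id or Path(path).stem,
        impact_index=impact_index,
    )


def series_frame(series: KinematicSeries) -> pd.DataFrame:
    """Kinematic series as a tidy data frame (one row per frame)."""
    return pd.DataFrame(
        {
            "time_s": series.time,
            "displacement_m": series.displacement,
            "deflection_rad": series.deflection,
            "linear_velocity_m_s": series.linear_velocity,
            "linear_acceleration_m_s2": series.linear_acceleration,
            "angular_velocity_rad_s": series.angular_velocity,
            "angular_acceleration_rad_s2": series.angular_acceleration,
        }
    )


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a tidy cohort table and check (animal, timepoint, measure) uniqueness."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks required columns {missing}")
    key = ["animal_id", "timepoint", "measure"]
    if df.duplicated(subset=key).any():
        raise ValueError("cohort table has duplicate (animal, timepoint, measure) rows")
    return df
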