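"""The Trajectory container and trajectory-table CSV I/O.

A trajectory is one tracked molecule's time-ordered positions (µm) at a
fixed frame period.  The on-disk format is a flat CSV with columns
``track_id, frame, x_um, y_um``, one row per localization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

CSV_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


@dataclass
class Trajectory:
    """Positions of one tracked molecule.

    ``frames`` is strictly increasing but may contain gaps (after linking
    with gap closing).  ``x`` and ``y`` are in µm.
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_period: float = 0.025

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least two points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames must be strictly increasing")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of positions in µm."""
        return np.column_stack([self.x, self.y])

    def gap_free(self) -> bool:
        return bool(np.all(np.diff(self.frames) == 1))


def tracks_to_frame(tracks: Iterable[Trajectory]) -> pd.DataFrame:
    rows = [
        pd.DataFrame(
            {
                "track_id": t.track_id,
                "frame": t.frames,
                "x_um": t.x,
                "y_um": t.y,
            }
        )
        for t in tracks
    ]
    if not rows:
        return pd.DataFrame(columns=CSV_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def frame_to_tracks(df: pd.DataFrame, frame_period: float = 0.025) -> List[Trajectory]:
    out = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        if len(sub) < 2:
            continue
        out.append(
            Trajectory(
                track_id=int(tid),
                frames=sub["frame"].to_numpy(),
                x=sub["x_um"].to_numpy(),
                y=sub["y_um"].to_numpy(),
                frame_period=frame_period,
            )
        )
    return out


def write_tracks_csv(tracks: Iterable[Trajectory], path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks_csv(path, frame_period: float = 0.025) -> List[Trajectory]:
    return frame_to_tracks(pd.read_csv(path), frame_period=frame_period)


class TrackValidationError(ValueError):
    pass


def validate_tracks(path, frame_period: float = 0.025) -> List[Trajectory]:
    """Load a trajectory CSV with schema and consistency checks.

    Hard failures: missing columns, non-numeric coordinates, frames that
    are not strictly increasing within a track.  Duplicate
    (track_id, frame) rows are reported in the error as well.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrackValidationError(f"{path}: missing required column(s) {missing}")
    bad = df[pd.to_numeric(df["x_um"], errors="coerce").isna()
             | pd.to_numeric(df["y_um"], errors="coerce").isna()]
    if len(bad):
        lines = (bad.index + 2).tolist()[:10]  # +2: header and 1-based
        raise TrackValidationError(f"{path}: non-numeric coordinates at line(s) {lines}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()[:10]
        raise TrackValidationError(f"{path}: duplicate (track_id, frame) rows at line(s) {lines}")
    for tid, sub in df.groupby("track_id"):
        fr = sub.sort_index()["frame"].to_numpy()
        if np.any(np.diff(fr) <= 0):
            raise TrackValidationError(f"{path}: track {tid} has non-increasing frames")
    return frame_to_tracks(df, frame_period=frame_period)
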