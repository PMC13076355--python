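"""Build per-animal-year trajectories from raw telemetry fixes.

Raw fixes carry one row per GPS *reading*; several readings of the same
relocation share a timestamp and are distinguished by ``reading_index``.
The field protocol collapses sub-meter movements onto the previous
coordinates and averages the first pair of readings that agree within 3 m.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UnresolvedFixError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "average_relocation",
    "build_trajectories",
    "derive_steps",
    "read_fixes",
    "read_relocations",
    "wrap_angle",
    "write_relocations",
]

FIX_COLUMNS = ["animal_id", "sex", "timestamp", "x", "y"]

#: Movements of at most this many meters are not unique locations.
MOVE_THRESHOLD_M = 1.0
#: Two readings must agree within this distance to be averaged.
PAIR_AGREEMENT_M = 3.0


def wrap_angle(a):
    """Wrap angles to the interval (-pi, pi]."""
    out = -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)
    return out


def average_relocation(readings, previous=None) -> np.ndarray:
    """Resolve one relocation from its GPS readings.

    If every reading is within 1 m of ``previous``, the animal is treated as
    stationary and the previous coordinates are returned unchanged.
    Otherwise the first pair of readings (in reading order) within 3 m of one
    another is averaged.  A lone reading more than 1 m from ``previous``
    cannot be confirmed and raises :class:`UnresolvedFixError`, as does a set
    of readings with no agreeing pair.
    """
    pts = np.asarray(readings, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 1:
        raise ValidationError("relocation with no readings")
    if previous is not None:
        prev = np.asarray(previous, dtype=float)
        d = np.hypot(pts[:, 0] - prev[0], pts[:, 1] - prev[1])
        if np.all(d <= MOVE_THRESHOLD_M):
            return prev.copy()
    if pts.shape[0] == 1:
        if previous is None:
            return pts[0].copy()
        raise UnresolvedFixError("single reading > 1 m from previous location with no confirming pair")
    for i in range(pts.shape[0] - 1):
        for j in range(i + 1, pts.shape[0]):
            if np.hypot(*(pts[i] - pts[j])) <= PAIR_AGREEMENT_M:
                return (pts[i] + pts[j]) / 2.0
    raise UnresolvedFixError("no two readings within 3 m of one another")


@dataclass
class Trajectory:
    """Ordered relocations of one animal within one calendar year."""

    animal_id: str
    sex: str
    year: int
    relocations: pd.DataFrame  # columns: timestamp, x, y, moved

    def points(self) -> np.ndarray:
        """All relocation coordinates, stationary repeats included."""
        return self.relocations[["x", "y"]].to_numpy(dtype=float)

    def unique_points(self) -> np.ndarray:
        """Coordinates of unique locations (first fix plus each move)."""
        moved = self.relocations["moved"].to_numpy(dtype=bool)
        keep = moved.copy()
        keep[0] = True
        return self.relocations.loc[keep, ["x", "y"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.relocations)


def read_fixes(path) -> pd.DataFrame:
    """Read a raw-fix table (CSV with header animal_id,sex,timestamp,x,y[,reading_index])."""
    df = pd.read_csv(path)
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"fix table missing columns: {missing}")
    if "reading_index" not in df.columns:
        df["reading_index"] = 0
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if df[["x", "y"]].isna().any().any():
        bad = df.index[df[["x", "y"]].isna().any(axis=1)].tolist()
        raise ValidationError(f"missing coordinates at rows {bad[:10]}")
    return df


def build_trajectories(fixes: pd.DataFrame) -> list[Trajectory]:
    """Resolve readings into relocations and split them into annual trajectories.

    Animal-years with fewer than two relocations, or without any movement
    beyond 1 m, are dropped with a warning.  Unresolvable fixes are excluded.
    """
    if "reading_index" not in fixes.columns:
        fixes = fixes.assign(reading_index=0)
    fixes = fixes.sort_values(["animal_id", "timestamp", "reading_index"], kind="stable")
    trajectories: list[Trajectory] = []
    for animal_id, group in fixes.groupby("animal_id", sort=True):
        sexes = group["sex"].unique()
        if len(sexes) != 1:
            raise ValidationError(f"animal {animal_id!r} has inconsistent sex labels {sexes.tolist()}")
        sex = str(sexes[0])
        prev = None
        rows = []
        for ts, readings in group.groupby("timestamp", sort=True):
            try:
                pt = average_relocation(readings[["x", "y"]].to_numpy(dtype=float), prev)
            except UnresolvedFixError as exc:
                warnings.warn(f"animal {animal_id} at {ts}: {exc}; fix excluded", stacklevel=2)
                continue
            moved = prev is not None and not np.array_equal(pt, prev)
            rows.append((ts, pt[0], pt[1], moved))
            prev = pt
        if not rows:
            continue
        reloc = pd.DataFrame(rows, columns=["timestamp", "x", "y", "moved"])
        for year, ygroup in reloc.groupby(reloc["timestamp"].dt.year, sort=True):
            ygroup = ygroup.reset_index(drop=True)
            ygroup.loc[0, "moved"] = False
            n_unique = 1 + int(ygroup["moved"].iloc[1:].sum())
            if len(ygroup) < 2 or n_unique < 2:
                log.warning(
                    "dropping %s/%s: %d relocations, %d unique locations",
                    animal_id, year, len(ygroup), n_unique,
                )
                continue
            trajectories.append(Trajectory(str(animal_id), sex, int(year), ygroup))
    return trajectories


def derive_steps(traj: Trajectory, movement_only: bool = True) -> pd.DataFrame:
    """Step sequence (start, end, length, heading, turn angle) for a trajectory.

    With ``movement_only`` the steps connect consecutive unique locations and
    every length is positive; otherwise they connect consecutive relocations
    and stationary steps have zero length and undefined heading.  The turn
    angle is measured against the last defined heading and is NaN for the
    first movement step.
    """
    pts = traj.unique_points() if movement_only else traj.points()
    d = np.diff(pts, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    headings = np.where(lengths > 0, np.arctan2(d[:, 1], d[:, 0]), np.nan)
    turns = np.full(len(lengths), np.nan)
    prev_heading = np.nan
    for i, h in enumerate(headings):
        if np.isnan(h):
            continue
        if not np.isnan(prev_heading):
            turns[i] = wrap_angle(h - prev_heading)
        prev_heading = h
    return pd.DataFrame(
        {
            "start_x": pts[:-1, 0],
            "start_y": pts[:-1, 1],
            "end_x": pts[1:, 0],
            "end_y": pts[1:, 1],
            "length": lengths,
            "heading": headings,
            "turn_angle": turns,
        }
    )


def write_relocations(trajectories, path) -> None:
    """Write trajectories as a delimited relocation table (with moved flag)."""
    frames = []
    for traj in trajectories:
        df = traj.relocations.copy()
        df.insert(0, "animal_id", traj.animal_id)
        df.insert(1, "sex", traj.sex)
        df.insert(2, "year", traj.year)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_relocations(path) -> list[Trajectory]:
    """Read back a relocation table written by :func:`write_relocations`."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for (animal_id, year), group in df.groupby(["animal_id", "year"], sort=True):
        reloc = group[["timestamp", "x", "y", "moved"]].reset_index(drop=True)
        out.append(Trajectory(str(animal_id), str(group["sex"].iloc[0]), int(year), reloc))
    return out
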