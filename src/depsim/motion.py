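"""Per-cell kinematics summaries from frame-by-frame track coordinates.

Motion-analysis software reduces each tracked cell to an average speed,
acceleration and coordinate position.  Reported speeds can be negative, so
"speed" here is a *signed* mean velocity: positions are projected onto the
track's principal displacement axis (the leading PCA direction of the
coordinates, oriented canonically toward +x) and velocity / acceleration
are mean finite differences of that projection.  A linearity flag records
whether the track is essentially one-dimensional (more than 95% of the
positional variance along the principal axis), in which case the projected
kinematics describe the full motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Track", "TrackSummary", "load_tracks", "summarize_track", "summarize_tracks"]

REQUIRED_COLUMNS = ("cell", "t_s", "x_um", "y_um")

#: Fraction of positional variance along the principal axis above which a
#: track counts as linear.
LINEARITY_THRESHOLD = 0.95


@dataclass(frozen=True)
class Track:
    """One cell's trajectory: strictly increasing times (s), positions (µm)."""

    label: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        p = np.asarray(self.positions, float)
        if t.ndim != 1 or t.size < 3:
            raise ValueError(f"track {self.label!r} needs at least 3 frames, got {t.size}")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"track {self.label!r} has non-increasing frame times")
        if p.shape != (t.size, 2):
            raise ValueError(f"track {self.label!r}: positions must be (n, 2)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)


@dataclass(frozen=True)
class TrackSummary:
    """Average signed speed (µm/s), acceleration (µm/s²), mean x (µm)."""

    label: str
    speed: float
    acceleration: float
    coordinate_position: float
    linear: bool


def load_tracks(path: str | Path) -> list[Track]:
    """Read tracks from a CSV with columns cell, t_s, x_um, y_um.

    Rows are grouped by cell label; within a cell, frames must already be in
    strictly increasing time order.  Validation failures report the
    offending rows (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    tracks = []
    for label, group in df.groupby("cell", sort=False):
        t = group["t_s"].to_numpy(float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            rows = (group.index[bad + 1] + 1).tolist()
            raise ValueError(
                f"{path}: non-increasing t_s for cell {label!r} at data rows {rows}"
            )
        tracks.append(
            Track(
                label=str(label),
                times=t,
                positions=group[["x_um", "y_um"]].to_numpy(float),
            )
        )
    return tracks


def _principal_axis(positions: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading PCA direction of the coordinates and its variance fraction.

    The axis is oriented canonically (positive x component; ties broken
    toward +y) so the sign of projected velocities does not depend on the
    direction of travel.
    """
    centred = positions - positions.mean(axis=0)
    cov = centred.T @ centred
    total = np.trace(cov)
    if total == 0.0:  # all frames coincide
        return np.array([1.0, 0.0]), 1.0
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis, float(evals[-1] / total)


def summarize_track(track: Track) -> TrackSummary:
    """Mean projected velocity, mean projected acceleration, mean x position."""
    axis, var_frac = _principal_axis(track.positions)
    s = track.positions @ axis          # µm along the principal axis
    dt = np.diff(track.times)
    vel = np.diff(s) / dt               # µm/s per interval
    t_mid = 0.5 * (track.times[:-1] + track.times[1:])
    acc = np.diff(vel) / np.diff(t_mid)  # µm/s² per interior frame
    return TrackSummary(
        label=track.label,
        speed=float(vel.mean()),
        acceleration=float(acc.mean()),
        coordinate_position=float(track.positions[:, 0].mean()),
        linear=var_frac > LINEARITY_THRESHOLD,
    )


def summarize_tracks(tracks: list[Track]) -> pd.DataFrame:
    """Summaries for many tracks as a tidy DataFrame."""
    rows = [summarize_track(t) for t in tracks]
    return pd.DataFrame(
        {
            "cell": [r.label for r in rows],
            "speed_um_s": [r.speed for r in rows],
            "accel_um_s2": [r.acceleration for r in rows],
            "coord_um": [r.coordinate_position for r in rows],
            "linear": [r.linear for r in rows],
        }
    )
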