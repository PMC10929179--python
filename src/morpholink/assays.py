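"""Motility and proliferation metrics from single-cell tracks and plate reads.

Speed is total path length over elapsed time (µm/min); persistence is the
net (start-to-finish Euclidean) displacement over the total path length,
which is 1 for perfectly straight motion and 0 for a closed loop.  Tracks
whose total path length falls below a resolution epsilon are flagged
stationary and assigned persistence 0.  Both metrics work identically for
2D and 3D coordinates and reduce exactly to the 2D value when z is
constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: total path length (µm) below which a track counts as stationary
STATIONARY_EPS_UM = 1.0


@dataclass
class Track:
    """Time-stamped positions of one cell.

    positions : (n, d) array of µm coordinates, d = 2 or 3.
    times_min : strictly increasing timestamps in minutes, length n.
    """

    cell_id: int | str
    positions: np.ndarray
    times_min: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be an (n, 2) or (n, 3) array")
        if self.positions.shape[0] < 2:
            raise ValueError("a track needs at least 2 positions")
        if self.times_min.shape != (self.positions.shape[0],):
            raise ValueError("times must match the number of positions")
        if not np.all(np.diff(self.times_min) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    @property
    def path_length(self) -> float:
        return float(self.step_lengths.sum())

    @property
    def net_displacement(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))


@dataclass
class MotilityRecord:
    cell_id: int | str
    speed: float  # µm/min
    persistence: float  # unitless, [0, 1]
    path_length: float  # µm
    net_displacement: float  # µm
    stationary: bool


def track_speed(track: Track) -> float:
    """Mean speed: total path length / elapsed time, µm/min."""
    elapsed = track.times_min[-1] - track.times_min[0]
    return track.path_length / elapsed


def track_persistence(track: Track, eps_um: float = STATIONARY_EPS_UM) -> float:
    """Directional persistence: net displacement / total path length.

    Stationary tracks (path length < ``eps_um``) return 0; use
    :func:`motility_record` to carry the stationary flag alongside.
    """
    path = track.path_length
    if path < eps_um:
        return 0.0
    return track.net_displacement / path


def motility_record(track: Track, eps_um: float = STATIONARY_EPS_UM) -> MotilityRecord:
    """Speed, persistence and path statistics for one track."""
    path = track.path_length
    stationary = path < eps_um
    return MotilityRecord(
        cell_id=track.cell_id,
        speed=track_speed(track),
        persistence=0.0 if stationary else track.net_displacement / path,
        path_length=path,
        net_displacement=track.net_displacement,
        stationary=stationary,
    )


def proliferation_fold_change(a24: float, a72: float) -> float:
    """Fold change in plate-reader absorbance between 24 h and 72 h."""
    if a24 <= 0 or a72 <= 0:
        raise ValueError("absorbances must be positive")
    return a72 / a24


def summarize_line(
    records: list[MotilityRecord],
    line: str | None = None,
    include_stationary: bool = True,
) -> pd.Series:
    """Per-line mean +/- SEM of speed and persistence.

    SEM uses the n-1 convention; for a single record it is undefined and
    reported as NaN.  Stationary-flagged cells are included by default and
    can be excluded (they then drop out of both metrics).
    """
    if not include_stationary:
        records = [r for r in records if not r.stationary]
    if len(records) == 0:
        raise ValueError("no records to summarize")
    speed = np.array([r.speed for r in records])
    pers = np.array([r.persistence for r in records])
    n = len(records)

    def sem(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")

    return pd.Series(
        {
            "line": line,
            "n": n,
            "speed_mean": speed.mean(),
            "speed_sem": sem(speed),
            "persistence_mean": pers.mean(),
            "persistence_sem": sem(pers),
        }
    )


def rose_bins(
    tracks: list[Track], n_bins: int = 8, eps_um: float = STATIONARY_EPS_UM
) -> tuple[np.ndarray, np.ndarray]:
    """Angular histogram of net-displacement directions (rose plot counts).

    Uses the x-y plane projection of each non-stationary track's
    start-to-finish vector.  Returns ``(counts, bin_edges)`` over
    [-pi, pi); counts sum to the number of non-stationary tracks.
    """
    if n_bins < 4:
        raise ValueError("need at least 4 angular bins")
    angles = []
    for t in tracks:
        delta = t.positions[-1] - t.positions[0]
        if t.path_length >= eps_um:
            angles.append(math.atan2(delta[1], delta[0]))
    edges = np.linspace(-math.pi, math.pi, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return counts, edges


# ---------------------------------------------------------------------------
# CSV interchange: columns cell_id, t_min, x_um, y_um[, z_um]

def tracks_to_csv(tracks: list[Track], path: str | Path) -> None:
    frames = []
    for t in tracks:
        cols = {"cell_id": t.cell_id, "t_min": t.times_min, "x_um": t.positions[:, 0],
                "y_um": t.positions[:, 1]}
        if t.positions.shape[1] == 3:
            cols["z_um"] = t.positions[:, 2]
        frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def tracks_from_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    coord_cols = ["x_um", "y_um"] + (["z_um"] if "z_um" in df.columns else [])
    tracks = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t_min")
        tracks.append(
            Track(
                cell_id=cell_id,
                positions=grp[coord_cols].to_numpy(),
                times_min=grp["t_min"].to_numpy(),
            )
        )
    return tracks
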