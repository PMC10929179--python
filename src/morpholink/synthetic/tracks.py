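"""Persistent random-walk tracks with a planted speed and persistence dial.

Cells step at constant speed and turn by an angle drawn from a wrapped
Cauchy distribution whose mean resultant length equals the persistence
parameter ``p``: p = 0 gives uniformly random turning (a simple random
walk), p = 1 no turning at all (a straight line).  This is the simplest
one-parameter family that interpolates between the two regimes; the
downstream net-over-total-path persistence metric is then a known, testable
function of (p, number of steps) by direct simulation.

In 3D the turning angle tilts the current direction by the same wrapped
Cauchy draw about a uniformly random perpendicular axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..assays import Track


@dataclass
class TrackSimParams:
    """Simulation settings for a batch of persistent random walks.

    speed_um_min : constant step speed, µm/min.
    persistence : p in [0, 1], concentration of the turning-angle
        distribution (0 uniform, 1 degenerate at zero turn).
    dt_min : sampling interval, minutes (default 20, a typical overnight
        live-imaging cadence).
    """

    n_tracks: int
    speed_um_min: float = 0.5
    persistence: float = 0.5
    dt_min: float = 20.0
    n_steps: int = 48
    ndim: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_tracks < 0:
            raise ValueError("n_tracks must be >= 0")
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must lie in [0, 1]")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.speed_um_min < 0:
            raise ValueError("speed must be >= 0")
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")


def _turning_angles(p: float, size: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    if p >= 1.0:
        return np.zeros(size)
    if p <= 0.0:
        return rng.uniform(-math.pi, math.pi, size=size)
    theta = stats.wrapcauchy.rvs(p, size=size, random_state=rng)
    return np.mod(theta + math.pi, 2.0 * math.pi) - math.pi


def _tracks_2d(params: TrackSimParams, rng: np.random.Generator) -> np.ndarray:
    n, m = params.n_tracks, params.n_steps
    headings = rng.uniform(-math.pi, math.pi, size=(n, 1))
    turns = _turning_angles(params.persistence, (n, m - 1), rng) if m > 1 else np.empty((n, 0))
    angles = headings + np.concatenate([np.zeros((n, 1)), np.cumsum(turns, axis=1)], axis=1)
    step = params.speed_um_min * params.dt_min
    dxy = step * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    pos = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(dxy, axis=1)], axis=1)
    return pos


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    # Rodrigues rotation of unit vector v about unit axis
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * np.dot(axis, v) * (1.0 - math.cos(angle))
    )


def _tracks_3d(params: TrackSimParams, rng: np.random.Generator) -> np.ndarray:
    n, m = params.n_tracks, params.n_steps
    step = params.speed_um_min * params.dt_min
    pos = np.zeros((n, m + 1, 3))
    turns = _turning_angles(params.persistence, (n, max(m - 1, 0)), rng)
    for i in range(n):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        for j in range(m):
            if j > 0:
                # random unit axis perpendicular to the current direction
                perp = np.cross(d, rng.normal(size=3))
                norm = np.linalg.norm(perp)
                while norm < 1e-12:
                    perp = np.cross(d, rng.normal(size=3))
                    norm = np.linalg.norm(perp)
                d = _rotate_about(d, perp / norm, turns[i, j - 1])
                d /= np.linalg.norm(d)
            pos[i, j + 1] = pos[i, j] + step * d
    return pos


def generate_tracks(params: TrackSimParams) -> list[Track]:
    """Simulate ``params.n_tracks`` persistent random walks.

    Each track has ``n_steps + 1`` positions at uniform ``dt_min`` spacing,
    starting at the origin, with every step exactly ``speed * dt`` long.
    With p = 1 every track is a straight line (persistence metric 1).
    """
    rng = np.random.default_rng(params.seed)
    if params.n_tracks == 0:
        return []
    pos = _tracks_2d(params, rng) if params.ndim == 2 else _tracks_3d(params, rng)
    times = np.arange(params.n_steps + 1) * params.dt_min
    return [Track(cell_id=i, positions=pos[i], times_min=times) for i in range(params.n_tracks)]
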