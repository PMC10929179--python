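"""Spheroid fixtures: peripheral cells at planted radial invasion distances."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class SpheroidPositions:
    """Peripheral cell coordinates (µm) of one spheroid plus its centre."""

    center: tuple[float, float]
    positions: np.ndarray  # (n, 2) µm
    distances: np.ndarray  # planted radial distances, µm
    core_radius_um: float


def generate_spheroid_positions(
    core_radius_um: float,
    invasion_distances_um: list[float] | np.ndarray,
    seed: int | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> SpheroidPositions:
    """Place peripheral cells at the given radial distances from the centre.

    Angles are drawn uniformly on [0, 2*pi), so the planted mean invasion
    distance of the spheroid is exactly ``mean(invasion_distances_um)``.
    An empty distance list is allowed and yields zero peripheral cells
    (downstream mean invasion is then undefined / NaN).
    """
    if core_radius_um <= 0:
        raise ValueError("core radius must be > 0")
    distances = np.asarray(invasion_distances_um, dtype=float)
    if np.any(distances < 0):
        raise ValueError("invasion distances must be >= 0")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 2.0 * math.pi, size=distances.size)
    positions = np.column_stack(
        [center[0] + distances * np.cos(angles), center[1] + distances * np.sin(angles)]
    )
    return SpheroidPositions(
        center=center,
        positions=positions,
        distances=distances,
        core_radius_um=core_radius_um,
    )
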