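"""Generate the synthetic study inputs with known ground truth.

Writes, under results/synthetic/:
  shape_truth.csv        analytic descriptors of a four-shape image panel
  tracks_grid.csv        persistent random walks over a persistence grid
  spheroid_positions.csv peripheral cells of one spheroid (planted distances)
  cohort6_features.csv / cohort6_outcomes.csv   six-line cohort
  planted_signs.csv      planted sign of every feature x outcome association
The rendered two-channel image itself goes to scratch/ (binary); script 02
re-renders it deterministically from the same seed before measuring.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from morpholink import assays
from morpholink.synthetic import (
    ShapeSpec,
    TrackSimParams,
    default_cohort_spec,
    generate_cohort,
    generate_shape_image,
    generate_spheroid_positions,
    generate_tracks,
)

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

PANEL_SPECS = [
    ShapeSpec("disk", (128, 128), 60, nucleus_radius=12),
    ShapeSpec("ellipse", (384, 128), (80, 45), rotation=0.6, nucleus_radius=12),
    ShapeSpec("rectangle", (128, 384), (110, 70), rotation=0.3, nucleus_radius=12),
    ShapeSpec("star", (384, 384), (85, 60), amplitude=0.3, n_lobes=6, nucleus_radius=12),
]
PERSISTENCE_GRID = [0.0, 0.25, 0.5, 0.75, 1.0]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    image, truth = generate_shape_image(PANEL_SPECS, (512, 512), pixel_size_um=1.0, seed=SEED)
    image.to_tiff(SCRATCH / "panel.tiff")
    truth.to_csv(OUT / "shape_truth.csv", index=False)
    print(f"image panel: {len(PANEL_SPECS)} silhouettes, truth table -> shape_truth.csv")

    frames = []
    for i, p in enumerate(PERSISTENCE_GRID):
        tracks = generate_tracks(
            TrackSimParams(n_tracks=500, persistence=p, n_steps=48, seed=SEED + i)
        )
        for t in tracks:
            frames.append(
                pd.DataFrame(
                    {
                        "persistence_param": p,
                        "cell_id": f"p{i}_{t.cell_id}",
                        "t_min": t.times_min,
                        "x_um": t.positions[:, 0],
                        "y_um": t.positions[:, 1],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(OUT / "tracks_grid.csv", index=False)
    print(f"tracks: 500 walks x {len(PERSISTENCE_GRID)} persistence levels -> tracks_grid.csv")

    sph = generate_spheroid_positions(200.0, np.linspace(250, 500, 40), seed=SEED)
    pd.DataFrame(sph.positions, columns=["x_um", "y_um"]).to_csv(
        OUT / "spheroid_positions.csv", index=False
    )
    print(f"spheroid: 40 peripheral cells, planted mean {sph.distances.mean():.1f} µm")

    spec = default_cohort_spec(n_lines=6, seed=SEED)
    features, outcomes = generate_cohort(spec)
    features.to_csv(OUT / "cohort6_features.csv")
    outcomes.to_csv(OUT / "cohort6_outcomes.csv")
    spec.planted_signs.to_csv(OUT / "planted_signs.csv")
    print(f"cohort: {features.shape[0]} lines x {features.shape[1]} features, "
          f"{outcomes.shape[1]} outcomes (latent shape-driven model)")


if __name__ == "__main__":
    main()
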