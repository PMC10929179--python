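"""Cell-line cohorts with a planted feature-outcome covariance structure.

Each synthetic cell line draws a latent "metastatic potential" u ~ N(0, 1);
every in vitro feature and in vivo outcome column is

    column = effect * u + noise,   noise ~ N(0, noise_sd^2) i.i.d.

so the planted sign of the (feature, outcome) association is
sign(effect_feature * effect_outcome) and the population correlation is

    rho = e_f * e_o / sqrt((e_f^2 + sd_f^2) * (e_o^2 + sd_o^2)).

The default effect pattern mirrors the qualitative structure reported for
TNBC panels: shape-irregularity descriptors (form factor, solidity) load
strongest on the latent factor, size descriptors load negatively, and the
motility/invasion metrics load only weakly - so shape should out-rank
motility in any faithful downstream association analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_NAMES = (
    "area_um2",
    "perimeter_um",
    "form_factor",
    "solidity",
    "eccentricity",
    "compactness",
    "proliferation_fold",
    "speed_2d",
    "persistence_2d",
    "speed_3d",
    "persistence_3d",
    "spheroid_fold",
)
OUTCOME_NAMES = ("tumor_volume_mm3", "lung_met_count", "liver_met_count")

#: loading of each default feature on the latent metastatic potential
_DEFAULT_FEATURE_EFFECTS = {
    "area_um2": -0.6,
    "perimeter_um": -0.6,
    "form_factor": 0.95,
    "solidity": 0.95,
    "eccentricity": -0.5,
    "compactness": -0.5,
    "proliferation_fold": 0.3,
    "speed_2d": 0.3,
    "persistence_2d": -0.3,
    "speed_3d": 0.3,
    "persistence_3d": -0.3,
    "spheroid_fold": 0.3,
}
_DEFAULT_OUTCOME_EFFECTS = {
    "tumor_volume_mm3": 0.9,
    "lung_met_count": 0.9,
    "liver_met_count": 0.95,
}


@dataclass
class CohortSpec:
    """Latent-factor cohort model.

    effect vectors are signed loadings of each column on the latent
    potential; ``noise_sd`` is the shared (or per-column) residual sd.
    All columns are on a z-like scale; the association layer standardizes
    anyway, so units are immaterial to correlation structure.
    """

    n_lines: int
    feature_names: tuple[str, ...] = FEATURE_NAMES
    outcome_names: tuple[str, ...] = OUTCOME_NAMES
    feature_effects: np.ndarray = field(
        default_factory=lambda: np.array([_DEFAULT_FEATURE_EFFECTS[f] for f in FEATURE_NAMES])
    )
    outcome_effects: np.ndarray = field(
        default_factory=lambda: np.array([_DEFAULT_OUTCOME_EFFECTS[o] for o in OUTCOME_NAMES])
    )
    noise_sd: float | np.ndarray = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        self.feature_effects = np.asarray(self.feature_effects, dtype=float)
        self.outcome_effects = np.asarray(self.outcome_effects, dtype=float)
        if self.feature_effects.shape != (len(self.feature_names),):
            raise ValueError("feature_effects must match feature_names")
        if self.outcome_effects.shape != (len(self.outcome_names),):
            raise ValueError("outcome_effects must match outcome_names")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be >= 0")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")

    @property
    def planted_signs(self) -> pd.DataFrame:
        """Sign of the planted association for every feature x outcome pair."""
        signs = np.sign(np.outer(self.feature_effects, self.outcome_effects)).astype(int)
        return pd.DataFrame(signs, index=list(self.feature_names), columns=list(self.outcome_names))


def default_cohort_spec(n_lines: int = 6, noise_sd: float = 0.4, seed: int | None = None) -> CohortSpec:
    """The standard shape-driven cohort (see module docstring)."""
    return CohortSpec(n_lines=n_lines, noise_sd=noise_sd, seed=seed)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort; returns (FeatureMatrix, OutcomeMatrix) DataFrames.

    Rows are cell lines (``line_00`` ...), in identical order in both
    frames.  The planted signs are available as ``spec.planted_signs``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lines
    latent = rng.normal(size=n)
    effects = np.concatenate([spec.feature_effects, spec.outcome_effects])
    n_cols = effects.size
    sd = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float), (n_cols,))
    data = np.outer(latent, effects) + rng.normal(size=(n, n_cols)) * sd
    index = pd.Index([f"line_{i:02d}" for i in range(n)], name="line")
    n_feat = len(spec.feature_names)
    features = pd.DataFrame(data[:, :n_feat], index=index, columns=list(spec.feature_names))
    outcomes = pd.DataFrame(data[:, n_feat:], index=index, columns=list(spec.outcome_names))
    return features, outcomes
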