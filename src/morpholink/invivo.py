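"""Tumour growth and metastatic burden from tabular animal records.

Input tables follow the caliper / histology workflow of orthotopic
xenograft studies: weekly length x width caliper reads per mouse, and per
organ (lung, liver) a list of lesion areas counted on stained sections.
The metastatic index normalises lesion count by primary tumour volume
(lesions per mm³); it is undefined for mice that never grew a palpable
tumour and such mice are excluded from index means.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

ORGANS = ("lung", "liver")

#: default palpability proxy for tumour latency, mm³
LATENCY_THRESHOLD_MM3 = 50.0


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumour volume, modified-ellipsoid convention V = L*W^2/2 (mm³).

    Length is the longer axis; if width exceeds length the two are swapped
    with a warning.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("caliper measurements must be positive")
    if width_mm > length_mm:
        warnings.warn("width > length; swapping axes", stacklevel=2)
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm**2 / 2.0


def metastatic_index(count: int, volume_mm3: float) -> float:
    """Lesions per mm³ of primary tumour; NaN when the volume is not positive.

    A NaN marks the index as undefined (e.g. a line that grew no palpable
    tumour) so it drops out of downstream means.
    """
    if count < 0:
        raise ValueError("lesion count must be >= 0")
    if volume_mm3 <= 0:
        return float("nan")
    return count / volume_mm3


def lesion_summary(
    lesions: pd.DataFrame,
    mice: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse/organ lesion counts and sizes, and per-line incidence.

    Parameters
    ----------
    lesions : one row per lesion, columns ``mouse_id``, ``organ``
        (lung/liver), ``lesion_area``.
    mice : one row per examined mouse, columns ``mouse_id``, ``line`` and
        optionally ``tumor_volume_mm3`` (enables the metastatic index).

    Returns
    -------
    per_mouse : one row per examined mouse x organ with ``count``,
        ``mean_size`` (NaN when no lesions) and, if volumes were given,
        ``metastatic_index``.
    per_line : per line x organ mean count, mean size, incidence
        (fraction of examined mice with >= 1 lesion) and mean index over
        mice with a defined index.
    """
    bad = set(lesions["organ"]) - set(ORGANS)
    if bad:
        raise ValueError(f"unknown organ(s) {sorted(bad)}; expected {ORGANS}")
    if (lesions["lesion_area"] <= 0).any():
        raise ValueError("lesion areas must be positive")
    grid = pd.MultiIndex.from_product(
        [mice["mouse_id"], ORGANS], names=["mouse_id", "organ"]
    ).to_frame(index=False)
    agg = (
        lesions.groupby(["mouse_id", "organ"])["lesion_area"]
        .agg(count="size", mean_size="mean")
        .reset_index()
    )
    per_mouse = grid.merge(agg, on=["mouse_id", "organ"], how="left")
    per_mouse["count"] = per_mouse["count"].fillna(0).astype(int)
    per_mouse = per_mouse.merge(mice, on="mouse_id", how="left")
    if "tumor_volume_mm3" in mice.columns:
        per_mouse["metastatic_index"] = [
            metastatic_index(c, v)
            for c, v in zip(per_mouse["count"], per_mouse["tumor_volume_mm3"])
        ]
    agg_map = {
        "mean_count": ("count", "mean"),
        "mean_size": ("mean_size", "mean"),
        "incidence": ("count", lambda c: (c > 0).mean()),
        "n_mice": ("count", "size"),
    }
    if "metastatic_index" in per_mouse.columns:
        agg_map["mean_index"] = ("metastatic_index", "mean")  # NaN-aware
    per_line = per_mouse.groupby(["line", "organ"]).agg(**agg_map).reset_index()
    return per_mouse, per_line


def growth_summary(
    volumes_mm3: np.ndarray | list[float],
    weeks: np.ndarray | list[int] | None = None,
    latency_threshold_mm3: float = LATENCY_THRESHOLD_MM3,
) -> tuple[int | None, float]:
    """Tumour latency and endpoint volume from a weekly volume series.

    Latency is the first week whose volume exceeds the threshold (a
    palpability proxy, default 50 mm³), or None if never reached; the
    endpoint volume is the last measurement.
    """
    volumes = np.asarray(volumes_mm3, dtype=float)
    if volumes.size < 1:
        raise ValueError("need at least one weekly measurement")
    weeks = np.arange(1, volumes.size + 1) if weeks is None else np.asarray(weeks)
    if weeks.shape != volumes.shape or not np.all(np.diff(weeks) > 0):
        raise ValueError("weeks must be increasing and match the volume series")
    above = np.flatnonzero(volumes > latency_threshold_mm3)
    latency = int(weeks[above[0]]) if above.size else None
    return latency, float(volumes[-1])
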