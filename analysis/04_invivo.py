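"""Tumour growth and metastatic burden on a simulated six-line mouse study.

Synthesizes per-mouse weekly caliper reads and per-organ lesion tables for
six cell lines spanning high to negligible tumorigenicity (one line never
grows a palpable tumour, so its metastatic index is undefined), then
computes growth summaries, lesion summaries, metastatic indices and Tukey
letters for endpoint volume.  Writes results/invivo/*.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from morpholink import association, invivo

OUT = Path(__file__).resolve().parents[1] / "results" / "invivo"
SEED = 0

# growth rate scale and weekly expected lesion burden per line
LINES = {
    "lineA_high": {"growth": 1.0, "lung_rate": 18, "liver_rate": 12, "size_um2": 9e4},
    "lineB_high": {"growth": 0.9, "lung_rate": 15, "liver_rate": 10, "size_um2": 6e4},
    "lineC_high": {"growth": 0.8, "lung_rate": 12, "liver_rate": 14, "size_um2": 5e4},
    "lineD_mid": {"growth": 0.45, "lung_rate": 2, "liver_rate": 9, "size_um2": 2e4},
    "lineE_mid": {"growth": 0.4, "lung_rate": 1, "liver_rate": 1, "size_um2": 1.5e4},
    "lineF_low": {"growth": 0.0, "lung_rate": 0.3, "liver_rate": 0.5, "size_um2": 1e4},
}
N_MICE = 8
N_WEEKS = 9


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    mice_rows, lesion_rows = [], []
    for line, p in LINES.items():
        for m in range(N_MICE):
            mouse = f"{line}_m{m}"
            scale = p["growth"] * rng.lognormal(0.0, 0.25)
            for week in range(1, N_WEEKS + 1):
                length = scale * week * 2.2
                width = 0.7 * length
                if length > 0.5:
                    mice_rows.append(
                        {"mouse_id": mouse, "line": line, "week": week,
                         "length_mm": length, "width_mm": width}
                    )
            endpoint = invivo.tumor_volume(scale * N_WEEKS * 2.2, 0.7 * scale * N_WEEKS * 2.2) \
                if scale * N_WEEKS * 2.2 > 0.5 else 0.0
            for organ in ("lung", "liver"):
                lam = p[f"{organ}_rate"] * max(endpoint, 20.0) / 1000.0
                for _ in range(rng.poisson(lam)):
                    lesion_rows.append(
                        {"mouse_id": mouse, "organ": organ,
                         "lesion_area": rng.lognormal(np.log(p["size_um2"]), 0.5)}
                    )
    mice = pd.DataFrame(mice_rows)
    lesions = pd.DataFrame(lesion_rows)
    mice.to_csv(OUT / "mice_weekly.csv", index=False)
    lesions.to_csv(OUT / "lesions.csv", index=False)

    # growth: latency + endpoint volume per mouse
    growth = []
    for (mouse, line), g in mice.sort_values("week").groupby(["mouse_id", "line"]):
        vols = [invivo.tumor_volume(l, w) for l, w in zip(g["length_mm"], g["width_mm"])]
        latency, endpoint = invivo.growth_summary(vols, g["week"].to_numpy())
        growth.append({"mouse_id": mouse, "line": line, "latency_week": latency,
                       "tumor_volume_mm3": endpoint})
    # mice that never produced a caliper read grew no tumour at all
    seen = {g["mouse_id"] for g in growth}
    for line, p in LINES.items():
        for m in range(N_MICE):
            mouse = f"{line}_m{m}"
            if mouse not in seen:
                growth.append({"mouse_id": mouse, "line": line, "latency_week": None,
                               "tumor_volume_mm3": 0.0})
    growth_df = pd.DataFrame(growth)
    growth_df.to_csv(OUT / "tumor_growth.csv", index=False)
    palpable = growth_df.groupby("line")["latency_week"].count()
    print("mice with palpable tumours per line:")
    print(palpable.to_string())

    per_mouse, per_line = invivo.lesion_summary(
        lesions, growth_df[["mouse_id", "line", "tumor_volume_mm3"]]
    )
    per_mouse.to_csv(OUT / "lesions_per_mouse.csv", index=False)
    per_line.to_csv(OUT / "lesions_per_line.csv", index=False)
    print("\nper-line lung burden (count, metastatic index, incidence):")
    print(per_line.query("organ == 'lung'")
          .set_index("line")[["mean_count", "mean_index", "incidence"]]
          .round(3).to_string())

    groups = {line: g["tumor_volume_mm3"].to_numpy() for line, g in growth_df.groupby("line")}
    tukey = association.anova_tukey(groups)
    letters = pd.Series(tukey.letters, name="differs_from")
    letters.to_csv(OUT / "volume_tukey_letters.csv")
    print(f"\nendpoint volume ANOVA p = {tukey.anova_p:.2e}; Tukey letters:")
    print(letters.to_string())


if __name__ == "__main__":
    main()
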