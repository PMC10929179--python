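# morpholink

Quantification pipeline linking the in vitro phenotype of tumour cell
lines to their in vivo behaviour in mouse xenografts, built around the
triple-negative breast cancer (TNBC) setting: panels of cell lines are
profiled by 2D cell-shape morphometry, single-cell motility in 2D and 3D,
proliferation and spheroid invasion, while matched xenograft cohorts
provide tumour volume and lung/liver metastatic burden. The association
layer then asks which in vitro metric best predicts the in vivo outcome.

Because raw imaging and animal data of such studies are rarely deposited,
the package ships a first-class synthetic-data module: silhouettes with
analytically known descriptors, persistent random walks with a planted
persistence parameter, spheroids with planted invasion distances, and
cell-line cohorts whose feature–outcome covariance is planted through a
latent "metastatic potential" factor. Every downstream stage is tested
against this ground truth.

## What is computed

**Shape descriptors** (per cell, from two-channel nuclei + F-actin
images; nucleus-seeded watershed segmentation, border cells discarded):

- area *A* (µm²) and perimeter *P* (µm, smoothed sub-pixel contour)
- form factor 4π*A*/*P*² — 1 for a circle, lower for protrusive outlines
- solidity *A*/*A*<sub>hull</sub> — 1 for convex shapes
- eccentricity of the moment-matched ellipse — 0 for a circle
- compactness 2π·MSD/*A* (MSD = mean squared pixel distance from the
  centroid) — 1 for a filled disk, larger for elongated/irregular shapes

**Motility** (per track): speed = path length / elapsed time (µm/min);
persistence = net displacement / path length ∈ [0, 1]; rose-plot binning
of net-displacement directions. **Proliferation**: absorbance fold change
A₇₂/A₂₄. **Spheroid invasion**: mean radial distance of peripheral
cells, as fold change over no-ECM controls.

**In vivo**: caliper tumour volume *V* = *L·W*²/2, tumour latency,
per-organ lesion counts/sizes, incidence, and the metastatic index
(lesions per mm³ of primary tumour; undefined for non-palpable tumours).

**Association**: per feature×outcome OLS fit (R², F-test p), Pearson *r*,
Spearman ρ (average ranks, exact permutation null for n ≤ 8); one-way
ANOVA with Tukey HSD and per-group letter annotations; PCA; and two-block
partial least squares (PLS2, NIPALS) scores/loadings capturing the
covariance between the in vitro block and the in vivo block.

## Worked example

```sh
morpholink demo --seed 3 --out demo/
```

simulates a 12-line cohort and writes the association grids and PLS
tables. The scripted analyses under `analysis/` run the same pipeline
stage by stage; `python analysis/05_associate.py` (after `01` and, for the
full chain, `02`–`04`) prints:

```
recovery over 200 cohorts (n_lines=50): all planted signs 100.0%,
shape ranked above motility 98.5%
```

i.e. on cohorts planted so that shape irregularity drives metastatic
outcome, the report recovers the sign of every planted association in all
replicates and ranks form factor/solidity above every motility metric
(by |ρ| against liver metastasis count) in 98.5% of replicates. The same
script also prints the six-line ranking, where sampling noise at n = 6
visibly scrambles the ordering — the small-panel caveat the per-line
design carries.

`python analysis/02_morphometry.py` reports the rasterization accuracy of
the descriptor chain on a four-shape panel (max relative error ≈ 3.7%,
on the form factor of a 110×70 px rectangle; ≤ 0.2% for areas).

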