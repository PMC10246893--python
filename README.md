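# skinmap

Spatially resolved immune phenotyping of skin sections from segmented
multiplex-imaging statistics.

Inflammatory skin conditions (lupus chilblains, Kawasaki-like syndromes,
COVID-associated acral lesions, ...) are routinely diagnosed from one or
two markers at a time, which misses the regional organisation of the
immune infiltrate. Multiplexed 3D confocal imaging of FFPE biopsies can
deliver ~10 markers per cell, but turning a table of segmented-cell
statistics — coordinates, morphology, per-channel mean fluorescence
intensity (MFI) — into an interpretable immune landscape requires an
analysis pipeline. `skinmap` is that pipeline, for the
dermato-immunology researcher or computational pathologist working
downstream of segmentation:

- **Cell-type annotation.** Binary marker-signature matrices (9 lymphoid
  + 10 myeloid subsets packaged) are *dynamically adapted* to each
  sample — every 1-entry becomes the channel's maximum observed MFI —
  and each cell is assigned the label of the signature with the highest
  Spearman ρ against its MFI vector; exact ties fall to `Other`.
- **Validation oracle.** A rule-based histo-cytometry gating hierarchy
  (the manual flow-cytometry-style reference) annotates the same cells
  independently; agreement is the regression coefficient R of per-label
  cell densities across the two routes (R between 0.75 and 1 indicates
  method agreement).
- **Activation status.** CD57 (T cells) and HLA-DR (dendritic cells)
  levels are split low/high at the first peak of the marker's density
  curve within each population; MFI z-scores are provided.
- **Spatial structure.** α-shapes (Delaunay simplices with circumradius
  ≤ 1/α) model the epidermis (α = 0.4 μm⁻¹) and detect inflammatory
  cell clusters (α = 0.1 μm⁻¹, ≥ 15 member cells); cell-to-epidermis
  distances use a k-d tree over the α-shape contour, with r = 0 inside
  the structure.
- **Quantification.** Cells/mm³ per subset, per-cluster composition,
  per-label mean distance to the epidermis, and tidy exports for
  external embedding/heatmap tools.
- **Synthetic data.** A generator with ground-truth labels, planted
  spatial clusters and an epidermis band makes every stage testable
  without imaging data (see `docs/methods.md` for the intensity model).

## Worked example

```sh
skinmap run-all --panel lymphoid --seed 7 --out-dir demo/
```

simulates a 708-cell lymphoid sample, annotates it by both routes,
splits activation states, models the epidermis, detects clusters and
writes every intermediate CSV. It ends with:

```
pipeline complete: concordance R = 0.858, 3 ROI(s); outputs in demo
```

meaning the matrix-annotation and gating-oracle densities agree with
R = 0.858 across the 9 lymphoid subsets (inside the validated 0.75–1
band) and three ≥15-cell inflammatory clusters were detected.
`demo/summary.csv` starts:

```
label,count,cells_per_mm3,mean_distance_um
B cell,20,4166.666666666667,215.10107425096766
NK cell,98,20416.666666666668,185.22551364780705
CD4 T CD57low,126,26250.000000000004,180.51558410716805
CD4 T CD57high,88,18333.333333333336,174.0499443488502
```

— counts per subset, densities over the 0.0048 mm³ imaged box, and mean
distance to the modelled epidermis in μm. `demo/activation_thresholds.csv`
records the first-peak CD57 cutoffs (here 1.51 and 1.10 a.u.: the first
density peak of a background-suppressed marker sits just above zero).

The same stages are available as library calls:

```python
import skinmap as sm

table = sm.read_cell_table("cells.csv")          # your export
matrix = sm.load_default_matrix("lymphoid")
annotated = sm.annotate_cells(table, sm.adapt_matrix(matrix, table))
density = sm.cell_density(annotated)             # cells/mm^3 per label
```

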