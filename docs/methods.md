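# Methods

`skinmap` analyses per-cell statistics exported from segmented 3D
multiplex confocal images of skin: one CSV row per CD45-segmented cell
with coordinates (μm), morphology and the mean fluorescence intensity
(MFI) of every channel. This note documents the models, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Cell-type annotation by rank correlation

An *attribution matrix* encodes one binary marker signature per
cell-type variant (entry 1 where the population expresses the marker).
A population that *can* express a marker owns two columns, one per
state (e.g. γδ T cells with and without CD4). Before scoring, the
matrix is **dynamically adapted** to the sample: every 1-entry is
replaced by the channel's maximum MFI observed in that sample, making
the signature columns commensurate with the data regardless of laser
power or detector gain.

Each cell's MFI vector is then correlated with every adapted column
using Spearman's ρ (average ranks for ties), computed over the matrix's
marker set only. The cell receives the label of the best-scoring
column. Columns sharing a label compete as variants — a tie between
them is not ambiguity — whereas an exact tie (scores equal after
rounding to 12 significant digits) across *different* labels, or an
all-constant MFI vector (ρ undefined), sends the cell to the sink label
`Other`.

A structural property of this scheme is worth stating plainly: because
a signature column carries tied zeros on all markers outside the
signature, a cell whose negative channels are continuous noise gives
those channels a random rank order, and any column whose signature is
one marker larger than the cell's true signature wins whenever that
extra channel happens to rank highest among the cell's `q` negative
channels — probability ≈ 1/q per such column. The discrimination of
the method therefore relies on negative channels being *tied at zero*,
which deconvolved, background-suppressed exports largely are. On
synthetic data this reproduces the known biases of the approach against
manual gating (inflation of supersets such as CD4⁺ T over dn T cells)
at realistic rates.

## Histo-cytometry gating oracle

The validation reference re-implements the manual flow-style hierarchy
as an ordered rule list (first match wins) over per-marker positivity
cutoffs; `low`/`high` requirements split a population at the same
cutoff. Rule order resolves the under-specified gates (mast cells,
gated only on tryptase, precede the granulocyte gates).

Cutoffs are supplied, not estimated, when ground truth is available: the
synthetic generator provides per-marker *expert gates* at the geometric
midpoint of the negative and positive intensity medians, emulating gates
drawn by an operator who has seen control stains. An automatic
derivation (`derive_gate_thresholds`) is also provided, with a
`valley` mode (density minimum between the first two modes of the
pooled per-marker KDE) and a `first_peak` mode (the activation rule
below). First-peak cutoffs sit at the centre of the background mode and
misgate roughly half of the truly-negative cells; they are kept for
completeness but are not the default oracle, and the valley mode
requires visible bimodality (a channel positive on every cell, such as
the pan-immune segmentation marker, has none — supply its gate
explicitly).

## Concordance measure

Agreement of the two annotation routes is the coefficient R (Pearson r
of the least-squares fit) of per-label cell densities, matrix route
regressed against gating route, across the label vocabulary. Densities
share the imaged-box volume (0.6 × 0.4 × 0.02 mm = 0.0048 mm³) as
denominator, so R is invariant to its value; the regression is refused
when fewer than 3 labels are populated. On the packaged benchmark, R is
typically 0.86–0.92 per panel and combined — inside the 0.75–1 band
that certifies agreement of the two methods.

## Activation status

Within each target population ({CD4 T, CD8 T} × CD57 and {dDC, LC,
CD207⁺ dDC} × HLA-DR by default), the marker's density curve is
estimated with a Gaussian KDE (Silverman's rule-of-thumb bandwidth,
0.9·min(sd, IQR/1.34)·n^(−1/5), on a 512-point grid spanning the data
range). The threshold is the MFI of the **first peak** of the curve,
scanning from low MFI; cells strictly above it are `high`, the rest
`low`. Numerical details: a peak is an interior strict local maximum
with density at least 5% of the global maximum (tail wiggles of a KDE
are strict local maxima too and must not count); a monotone-decreasing
curve peaks at the first grid point; populations under 10 cells or with
zero spread are left unsplit with a warning.

**Known limitation.** The first-peak rule places the cutoff at the
centre of the negative mode, not in the valley, so for a continuous
unimodal negative component roughly Φ(σ) of its mass (40–60%) lies
above the cutoff. Consequently the recovered high fraction of a 50/50
mixture of two well-separated log-normals is ~0.74, not 0.50: the rule
*over-calls* positivity by ≈ half the negative mass above the first
peak. When negatives pile up at exactly zero (deconvolved data), the
first peak is the zero spike, the cutoff is ~0, and the overcall shrinks
to the non-zero background fraction divided by two. The rule is
implemented as published; the acceptance suite records the mixture
recovery check as an honest failure rather than substituting a
valley-based rule that would pass it.

MFI z-scores are `(x − mean)/sd` with the n−1 divisor (the `scale()`
convention), computed over whatever cell set the caller passes.

## α-shapes, clusters and distances

The α-shape of a point set is built from its Delaunay triangulation by
keeping the simplices with circumradius ≤ 1/α and dissolving shared
edges; α = 0 keeps everything (convex hull), larger α gives tighter and
possibly disconnected shapes. α is in μm⁻¹. Duplicate points are
removed before triangulation; collinear input yields an empty shape
with a warning. Areas are exact polygon areas of the union.

*Inflammatory clusters* (ROIs) are the disjoint polygons of the
α-shape over all cell positions at α = 0.1 (10 μm circumradius cap).
Membership is point-in-polygon with the boundary counting as inside; a
measure-zero boundary tie goes to the lower ROI id. Candidates with
fewer than 15 member cells are discarded — the published minimum
cluster size separating inflamed from healthy-looking tissue. Survivors
carry area, member ids, per-label composition (proportions summing
to 1) and the unweighted centroid. Note that at inflamed-tissue cell
densities (~3·10⁻³ cells/μm²) uniform position noise alone produces
occasional ≥15-cell clusters at α = 0.1; the parameter is tuned for
exactly that regime and both α and the size cutoff are configurable.

The *epidermis* is modelled as the α-shape (α = 0.4, i.e. 2.5 μm
circumradius) of densely sampled surface points projected to x-y; its
boundary vertices are indexed in a k-d tree. A cell's distance to the
structure is 0 if the cell lies inside or on the shape, else the
distance to the nearest contour vertex — by construction of the index,
not to edge interiors; the contour sampling density (2 μm in the
generator) bounds the discrepancy.

## Synthetic data: what it emulates, what it does not

The generator draws each cell's channels from log-normal distributions:
positive markers from a per-marker brightness ladder (medians
150 × 2.2^k a.u., dimmest to brightest, CD45 brightest — fluorochrome
and antibody brightness genuinely span decades), negative background
with median 8 a.u., both with sdlog 0.35 (≈ 10 sdlog separation). A
fraction π₀ = 0.85 of truly-negative cell×channel values is exactly 0,
emulating deconvolution background suppression; as discussed above this
zero-inflation is what any rank-correlation annotator needs, and the
annotation-vs-gating concordance degrades smoothly as π₀ drops (R ≈ 0.1
at π₀ = 0.5). Subset counts default to 708 lymphoid + 519 myeloid
cells — the benchmark scale of one pair of serially sectioned panels.
Positions are uniform in the 600 × 400 × 20 μm box plus optional
Gaussian blobs; the epidermis is a 30 μm band sampled at 2 μm spacing.
A `zero_noise` variant degenerates negatives to 0 and positives to
their medians, making both annotation routes provably exact — the
calibration point of the pipeline.

Not emulated: spatial intensity gradients, spectral spillover residues,
segmentation errors (merged/split cells), cell-size–intensity coupling,
autofluorescence correlated across channels, and 3D structure beyond a
uniform z. Passing benchmarks therefore certify the *algorithms* under
the stated statistical model, not performance on any particular imaging
dataset; the concordance band matching published values on real tissue
is a consistency check, not a proof of equivalence.

Problem sizes used throughout the test and acceptance suites (1,227
benchmark cells, 2,000-cell activation mixtures, 465-cell cluster
sweeps, ~4,800-point epidermis contours) keep every suite in seconds
while leaving all rates measurable at the stated tolerances.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `alpha_roi` | 0.1 μm⁻¹ | cluster α (10 μm circumradius cap) |
| `alpha_epidermis` | 0.4 μm⁻¹ | epidermis α (2.5 μm cap) |
| `min_roi_cells` | 15 | minimum cluster membership |
| `kde_grid_points` | 512 | density-curve grid |
| ROI volume | 0.0048 mm³ | imaged box 0.6 × 0.4 × 0.02 mm |
| tie precision | 12 significant digits | ρ equality for `Other` |
| peak floor | 5% of max density | spurious-peak rejection |
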