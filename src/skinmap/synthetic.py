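"""Synthetic single-cell databases with known ground truth.

The generator emulates the statistical structure of per-cell statistics
exported from segmented multiplex confocal images of skin:

* **Marker intensities.**  Each cell draws every channel from a
  log-normal distribution — the positive one of its subset signature or
  the negative background — with per-marker positive medians spread over
  a brightness ladder (fluorochrome and antibody brightness genuinely
  span more than a decade in such panels).  A configurable fraction of
  truly-negative cell×channel values is exactly 0, emulating the
  background suppression of deconvolution: those exact zeros produce the
  tied ranks that make rank-correlation annotation discriminative, and
  are a real feature of deconvolved exports.
* **Space.**  Cells live in an imaged box of 600 × 400 μm × 20 μm (the
  acquisition volume of one region of interest); positions are uniform
  background plus optional Gaussian blobs emulating inflammatory
  clusters.
* **Epidermis.**  A band of densely sampled surface points along one
  edge of the box stands in for the epidermal autofluorescence surface.

Ground truth (labels, gate positions) is returned *alongside* the cell
table, never inside it.  All outputs are reproducible from the spec's
seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AttributionMatrix, CellTable, EpidermisContour, ValidationError, load_default_matrix

#: imaged-box extents of one acquisition, μm
DEFAULT_ROI_BOX = (600.0, 400.0, 20.0)

#: per-panel marker order from dimmest to brightest positive median
BRIGHTNESS_ORDER = {
    "lymphoid": ["CD57", "TCRgd", "CD20", "CD8", "CD4", "CD3", "CD45"],
    "myeloid": ["CD123", "Siglec8", "MPO", "Tryptase", "CD1c", "CD207", "HLA-DR", "CD45"],
}
BRIGHTNESS_BASE = 150.0   # dimmest positive median, a.u.
BRIGHTNESS_RATIO = 2.2    # ladder step between adjacent markers
NEGATIVE_MEDIAN = 8.0     # background median, a.u.
DEFAULT_SDLOG = 0.35
NEGATIVE_ZERO_FRACTION = 0.85  # deconvolution zeroes most empty channels

#: default subset counts: 708 lymphoid + 519 myeloid cells, the cell
#: yield of one lymphoid + one myeloid serial section at benchmark scale
DEFAULT_COUNTS = {
    "lymphoid": {
        "CD4 T CD57low": 200, "CD4 T CD57high": 60,
        "CD8 T CD57low": 150, "CD8 T CD57high": 90,
        "gd T cell": 40, "dn T cell": 30, "dp T cell": 18,
        "B cell": 20, "NK cell": 100,
    },
    "myeloid": {
        "Mast cell": 90, "Neutrophil": 120, "Eosinophil": 60, "Basophil": 15,
        "dDC HLA-DRlow": 60, "dDC HLA-DRhigh": 80,
        "LC HLA-DRlow": 40, "LC HLA-DRhigh": 30,
        "CD207+ dDC HLA-DRlow": 14, "CD207+ dDC HLA-DRhigh": 10,
    },
}


@dataclass
class IntensityModel:
    """Log-normal positive/negative intensity parameters of one marker."""

    pos_meanlog: float
    pos_sdlog: float = DEFAULT_SDLOG
    neg_meanlog: float = float(np.log(NEGATIVE_MEDIAN))
    neg_sdlog: float = DEFAULT_SDLOG
    neg_zero_fraction: float = NEGATIVE_ZERO_FRACTION

    def __post_init__(self) -> None:
        if self.pos_meanlog <= self.neg_meanlog:
            raise ValidationError("positive meanlog must exceed negative meanlog")

    @property
    def midpoint_gate(self) -> float:
        """Geometric midpoint of the two medians: the expert gate position."""
        return float(np.exp(0.5 * (self.pos_meanlog + self.neg_meanlog)))


@dataclass
class Blob:
    """A Gaussian spatial cluster of cells."""

    center: tuple[float, float]
    sd: float
    n: int
    labels: tuple[str, ...] | None = None  # restrict membership; None = any


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic sample."""

    panel: AttributionMatrix
    subset_counts: dict[str, int]
    intensity: dict[str, IntensityModel]
    activation_mix: dict[tuple[str, str], float] = field(default_factory=dict)
    blobs: list[Blob] = field(default_factory=list)
    roi_box: tuple[float, float, float] = DEFAULT_ROI_BOX
    epidermis_band: tuple[float, float] | None = (0.0, 30.0)
    epidermis_spacing: float = 2.0
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.subset_counts.values()):
            raise ValidationError("subset counts must be >= 0")
        for m in self.panel.markers:
            if m not in self.intensity:
                raise ValidationError(f"no intensity model for marker {m}")
        bx, by, _ = self.roi_box
        for blob in self.blobs:
            if not (0 <= blob.center[0] <= bx and 0 <= blob.center[1] <= by):
                raise ValidationError(f"blob at {blob.center} outside the box")


@dataclass
class SyntheticSample:
    """A generated sample with its ground truth."""

    table: CellTable
    truth: pd.Series                 # cell_id -> true label
    contour: EpidermisContour | None
    reference_gates: dict[str, float]
    spec: SyntheticSpec


def default_intensity_models(panel: str) -> dict[str, IntensityModel]:
    """The packaged brightness ladder for a panel's markers."""
    order = BRIGHTNESS_ORDER[panel]
    return {
        m: IntensityModel(pos_meanlog=float(np.log(BRIGHTNESS_BASE * BRIGHTNESS_RATIO ** k)))
        for k, m in enumerate(order)
    }


def zero_noise(spec: SyntheticSpec) -> SyntheticSpec:
    """Return a noiseless variant: negatives exactly 0, positives fixed.

    With degenerate intensities every cell's MFI vector is an exact
    rescaling of its signature, so both annotation routes must recover
    the ground truth perfectly — the calibration point of the pipeline.
    """
    intensity = {m: replace(im, pos_sdlog=0.0, neg_zero_fraction=1.0)
                 for m, im in spec.intensity.items()}
    return replace(spec, intensity=intensity)


def _signature_for(label: str, panel: AttributionMatrix) -> set[str]:
    for cid, lab in panel.column_labels.items():
        if lab == label:
            return panel.signature(cid)  # canonical (first) variant
    raise ValidationError(f"label {label!r} not present in panel {panel.panel_name!r}")


def _expand_counts(spec: SyntheticSpec) -> list[str]:
    """Expand subset counts (with activation mixing) into per-cell labels."""
    labels: list[str] = []
    for label, n in spec.subset_counts.items():
        mix = [(m, f) for (base, m), f in spec.activation_mix.items() if base == label]
        if mix:
            marker, frac = mix[0]
            n_high = round(frac * n)
            labels += [f"{label} {marker}high"] * n_high
            labels += [f"{label} {marker}low"] * (n - n_high)
        else:
            labels += [label] * n
    return labels


def generate_sample(spec: SyntheticSpec) -> SyntheticSample:
    """Draw one sample from a spec; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    labels = _expand_counts(spec)
    n = len(labels)
    if n == 0:
        raise ValidationError("spec generates no cells")

    # signatures: resolve split labels ("X <marker>high") via the panel
    signatures = []
    for lab in labels:
        if lab in panel.labels:
            signatures.append(_signature_for(lab, panel))
        else:
            base, suffix = lab.rsplit(" ", 1)
            marker = suffix[:-len("high")] if suffix.endswith("high") else suffix[:-len("low")]
            sig = _signature_for(base, panel)
            signatures.append(sig | {marker} if suffix.endswith("high") else sig - {marker})

    X = np.zeros((n, len(panel.markers)))
    for j, m in enumerate(panel.markers):
        im = spec.intensity[m]
        pos = np.array([m in s for s in signatures])
        if im.pos_sdlog == 0:
            X[pos, j] = np.exp(im.pos_meanlog)
        else:
            X[pos, j] = rng.lognormal(im.pos_meanlog, im.pos_sdlog, int(pos.sum()))
        n_neg = int((~pos).sum())
        neg = rng.lognormal(im.neg_meanlog, im.neg_sdlog, n_neg) if im.neg_sdlog > 0 \
            else np.full(n_neg, np.exp(im.neg_meanlog))
        neg[rng.random(n_neg) < im.neg_zero_fraction] = 0.0
        X[~pos, j] = neg

    # positions: uniform background, then blobs claim cells
    bx, by, bz = spec.roi_box
    xy = rng.uniform([0, 0], [bx, by], (n, 2))
    z = rng.uniform(0, bz, n)
    free = np.ones(n, dtype=bool)
    labels_arr = np.array(labels, dtype=object)
    for blob in spec.blobs:
        eligible = free if blob.labels is None else \
            free & np.isin(labels_arr, list(blob.labels))
        take = np.nonzero(eligible)[0][:blob.n]
        if len(take) < blob.n:
            raise ValidationError(f"not enough free cells for blob at {blob.center}")
        xy[take] = np.clip(rng.normal(blob.center, blob.sd, (len(take), 2)),
                           0, [bx, by])
        free[take] = False

    cells = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "x": xy[:, 0], "y": xy[:, 1], "z": z,
        "volume": rng.lognormal(np.log(150.0), 0.3, n),
        "sphericity": rng.uniform(0.6, 0.95, n),
        "area": rng.lognormal(np.log(120.0), 0.3, n),
    })
    for j, m in enumerate(panel.markers):
        cells[m] = X[:, j]
    table = CellTable(spec.sample_id, cells, list(panel.markers))

    contour = None
    if spec.epidermis_band is not None:
        y0, y1 = spec.epidermis_band
        s = spec.epidermis_spacing
        gx, gy = np.meshgrid(np.arange(0, bx + s / 2, s), np.arange(y0, y1 + s / 2, s))
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        pts += rng.uniform(-0.1, 0.1, pts.shape)  # break exact co-circularity
        contour = EpidermisContour(np.column_stack([pts, np.full(len(pts), bz / 2)]))

    gates = {m: spec.intensity[m].midpoint_gate for m in panel.markers}
    truth = pd.Series(labels_arr, index=cells["cell_id"], name="true_label")
    return SyntheticSample(table, truth, contour, gates, spec)


# ---------------------------------------------------------------------------
# benchmark suite
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkCase:
    name: str
    sample: SyntheticSample
    expected: dict


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, n)]


def benchmark_panel_spec(panel: str, seed: int) -> SyntheticSpec:
    """The packaged well-separated benchmark sample for one panel."""
    return SyntheticSpec(
        panel=load_default_matrix(panel),
        subset_counts=dict(DEFAULT_COUNTS[panel]),
        intensity=default_intensity_models(panel),
        seed=seed,
        sample_id=f"benchmark_{panel}",
    )


def generate_benchmark_suite(seed: int) -> dict[str, BenchmarkCase]:
    """The fixed fixture set exercised by the acceptance checks.

    Regenerating with the same seed yields identical fixtures.
    """
    seeds = _child_seeds(seed, 8)
    cases: dict[str, BenchmarkCase] = {}

    for k, panel in enumerate(("lymphoid", "myeloid")):
        spec = benchmark_panel_spec(panel, seeds[k])
        sample = generate_sample(spec)
        cases[panel] = BenchmarkCase(panel, sample, {
            "n_cells": sum(DEFAULT_COUNTS[panel].values()),
            "subset_counts": dict(DEFAULT_COUNTS[panel]),
        })
        noiseless = generate_sample(zero_noise(replace(spec, seed=seeds[k + 2])))
        cases[f"{panel}_zero_noise"] = BenchmarkCase(
            f"{panel}_zero_noise", noiseless,
            {"n_cells": sum(DEFAULT_COUNTS[panel].values())})

    # bimodal activation sample: one T-cell population, CD57 a 50/50
    # mixture of two well-separated log-normals (modes near 10 and 100)
    lym = load_default_matrix("lymphoid")
    intensity = default_intensity_models("lymphoid")
    intensity["CD57"] = IntensityModel(
        pos_meanlog=float(np.log(100.0)), pos_sdlog=0.25,
        neg_meanlog=float(np.log(10.0)), neg_sdlog=0.25, neg_zero_fraction=0.0)
    act_spec = SyntheticSpec(
        panel=lym,
        subset_counts={"CD4 T": 2000},
        intensity=intensity,
        activation_mix={("CD4 T", "CD57"): 0.5},
        seed=seeds[4],
        sample_id="activation_bimodal",
    )
    cases["activation_bimodal"] = BenchmarkCase(
        "activation_bimodal", generate_sample(act_spec),
        {"high_fraction": 0.5, "low_mode": 10.0, "high_mode": 100.0})

    # filter sweep: isolated tight blobs of sizes 1..30 on a 200 μm grid
    sizes = list(range(1, 31))
    centers = [(100.0 + 200.0 * (i % 6), 100.0 + 200.0 * (i // 6)) for i in range(30)]
    sweep_spec = SyntheticSpec(
        panel=lym,
        subset_counts={"dn T cell": sum(sizes)},
        intensity=default_intensity_models("lymphoid"),
        blobs=[Blob(center=c, sd=2.0, n=k) for k, c in zip(sizes, centers)],
        roi_box=(1300.0, 1100.0, 20.0),
        epidermis_band=None,
        seed=seeds[5],
        sample_id="roi_filter_sweep",
    )
    cases["roi_filter_sweep"] = BenchmarkCase(
        "roi_filter_sweep", generate_sample(sweep_spec),
        {"blob_sizes": sizes, "retained_sizes": list(range(15, 31)),
         "blob_sd": 2.0, "separation": 200.0})

    # planted blobs over sparse background: exact cluster-count recovery
    planted_spec = SyntheticSpec(
        panel=lym,
        subset_counts={"CD8 T CD57high": 90, "dn T cell": 60},
        intensity=default_intensity_models("lymphoid"),
        blobs=[Blob(center=(100.0, 100.0), sd=2.5, n=20),
               Blob(center=(300.0, 250.0), sd=2.5, n=30),
               Blob(center=(500.0, 120.0), sd=2.5, n=40)],
        epidermis_band=None,
        seed=seeds[6],
        sample_id="planted_blobs",
    )
    cases["planted_blobs"] = BenchmarkCase(
        "planted_blobs", generate_sample(planted_spec), {"n_rois": 3})

    # two populations at known distances from the epidermis band
    dist_spec = SyntheticSpec(
        panel=lym,
        subset_counts={"CD8 T CD57high": 60, "CD8 T CD57low": 60},
        intensity=default_intensity_models("lymphoid"),
        epidermis_band=(0.0, 30.0),
        seed=seeds[7],
        sample_id="epidermis_distance",
    )
    sample = generate_sample(dist_spec)
    cells = sample.table.cells
    near = sample.truth.to_numpy() == "CD8 T CD57high"
    cells.loc[near, "y"] = 40.0   # 10 μm below the band edge at y = 30
    cells.loc[~near, "y"] = 130.0  # 100 μm below
    cells.loc[:, "x"] = np.linspace(20.0, 580.0, len(cells))
    cases["epidermis_distance"] = BenchmarkCase(
        "epidermis_distance", sample,
        {"near_label": "CD8 T CD57high", "near_distance": 10.0,
         "far_label": "CD8 T CD57low", "far_distance": 100.0})
    return cases
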