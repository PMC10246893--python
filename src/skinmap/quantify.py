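"""Sample-level quantification: densities, distance summaries, exports."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .attribution import OTHER_LABEL, AnnotationResult
from .clusters import AlphaROI
from .geometry import DistanceTable
from .io import CellTable, ValidationError

#: volume of the default imaged box, 0.6 x 0.4 x 0.02 mm
DEFAULT_ROI_VOLUME_MM3 = 0.0048


def cell_density(
    annotation: AnnotationResult,
    roi_volume_mm3: float = DEFAULT_ROI_VOLUME_MM3,
    include_other: bool = False,
) -> pd.Series:
    """Cells per mm³ for every label of the annotation vocabulary.

    Zero-count labels are reported (with density 0).  "Other" cells stay
    in the total cell count but are excluded from per-label densities
    unless requested.
    """
    if roi_volume_mm3 <= 0:
        raise ValidationError("roi_volume_mm3 must be positive")
    counts = annotation.label_counts(include_other=include_other)
    return (counts / roi_volume_mm3).rename("cells_per_mm3")


def distance_summary(annotation: AnnotationResult, distances: DistanceTable) -> pd.Series:
    """Arithmetic mean distance to the structure (μm) per label.

    Labels with no cells are omitted.  Requires the two tables to carry
    exactly the same cell ids.
    """
    ann = annotation.cells[["cell_id", "label"]]
    dist = distances.distances[["cell_id", "distance_um"]]
    if len(ann) != len(dist) or set(ann["cell_id"]) != set(dist["cell_id"]):
        raise ValidationError("annotation and distance tables are misaligned")
    merged = ann.merge(dist, on="cell_id")
    return merged.groupby("label")["distance_um"].mean().rename("mean_distance_um")


def export_embedding_inputs(
    annotation: AnnotationResult, table: CellTable, path: str | Path
) -> pd.DataFrame:
    """Write the per-cell feature matrix + label column for external
    embedding/heatmap tools (t-SNE, PCA, clustered heatmaps).

    No embedding is computed here; the export is the hand-off point.
    """
    merged = table.cells[["cell_id"] + table.channels].merge(
        annotation.cells[["cell_id", "label"]], on="cell_id")
    merged.to_csv(path, index=False)
    return merged


@dataclass
class SampleSummary:
    """Per-sample quantification bundle."""

    sample_id: str
    roi_volume_mm3: float
    n_cells: int
    per_label: pd.DataFrame        # label, count, density, mean distance
    n_rois: int
    roi_density_per_mm3: float


def summarize_sample(
    sample_id: str,
    annotation: AnnotationResult,
    distances: DistanceTable | None = None,
    rois: list[AlphaROI] | None = None,
    roi_volume_mm3: float = DEFAULT_ROI_VOLUME_MM3,
) -> SampleSummary:
    """Assemble counts, densities and mean distances into one table."""
    counts = annotation.label_counts(include_other=True)
    density = counts / roi_volume_mm3
    per_label = pd.DataFrame({"label": counts.index,
                              "count": counts.to_numpy(),
                              "cells_per_mm3": density.to_numpy()})
    if distances is not None:
        means = distance_summary(annotation, distances)
        per_label["mean_distance_um"] = per_label["label"].map(means)
    rois = rois or []
    return SampleSummary(
        sample_id=sample_id,
        roi_volume_mm3=roi_volume_mm3,
        n_cells=annotation.n_cells,
        per_label=per_label,
        n_rois=len(rois),
        roi_density_per_mm3=len(rois) / roi_volume_mm3,
    )
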