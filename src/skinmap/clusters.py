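"""Detection of inflammatory immune clusters (α-shape ROIs).

An α-shape with a tuned α (default 0.1 /μm, i.e. a 10 μm circumradius
cap) computed over all annotated cell positions breaks a sample into
disjoint candidate polygons of high cell density.  Candidates with fewer
than ``min_cells`` members (default 15 — the cluster size seen in
inflamed but not healthy-looking skin) are discarded; survivors become
ROIs with an area, a member set, a per-label composition and a centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .attribution import AnnotationResult
from .geometry import alpha_shape
from .io import CellTable, ValidationError


@dataclass
class AlphaROI:
    """One detected inflammatory cluster."""

    roi_id: int
    polygon: Polygon
    area: float                    # μm²
    member_cell_ids: list[int]
    composition: pd.DataFrame      # label, count, proportion
    center: tuple[float, float]    # unweighted mean of member coordinates, μm

    @property
    def n_cells(self) -> int:
        return len(self.member_cell_ids)


def detect_alpha_rois(
    table: CellTable,
    annotation: AnnotationResult,
    alpha: float = 0.1,
    min_cells: int = 15,
) -> list[AlphaROI]:
    """Detect ROIs over the cell positions of one annotated sample.

    Membership is point-in-polygon (boundary inclusive); a cell on the
    shared boundary of two polygons is assigned to the lower roi_id for
    determinism.  Cells in no surviving polygon are "unclustered": kept
    in the sample, absent from ROI statistics.  An empty list is a valid
    outcome (healthy-like sample).
    """
    if table.n_cells < 3:
        return []
    if len(annotation.cells) != table.n_cells:
        raise ValidationError("annotation does not match table")

    xy = table.positions("xy")
    shape = alpha_shape(xy, alpha)
    labels = annotation.cells.set_index("cell_id")["label"]
    cell_ids = table.cells["cell_id"].to_numpy()

    rois: list[AlphaROI] = []
    assigned = np.zeros(len(xy), dtype=bool)
    for poly in shape.polygons:  # deterministic component order
        from shapely import covers, points as mk_points
        member = covers(poly, mk_points(xy)) & ~assigned
        if member.sum() < min_cells:
            # candidate below the minimum size: dropped, cells stay free
            continue
        assigned |= member
        ids = cell_ids[member]
        member_labels = labels.loc[ids]
        counts = member_labels.value_counts().sort_index()
        comp = pd.DataFrame({
            "label": counts.index,
            "count": counts.to_numpy(),
            "proportion": counts.to_numpy() / counts.sum(),
        })
        center = tuple(xy[member].mean(axis=0))
        rois.append(AlphaROI(
            roi_id=len(rois) + 1,
            polygon=poly,
            area=float(poly.area),
            member_cell_ids=[int(i) for i in ids],
            composition=comp,
            center=(float(center[0]), float(center[1])),
        ))
    return rois


def roi_summary(
    rois: list[AlphaROI],
    sample_area_mm2: float | None = None,
    sample_volume_mm3: float | None = None,
    sample_id: str = "",
) -> dict:
    """Sample-level ROI statistics.

    Returns the ROI count, the density per mm² (and per mm³ when a
    volume is given) and a tidy per-ROI composition table suitable for
    cross-sample heatmaps.  The per-area denominator is the default; the
    per-volume one is available because thick-section counts are often
    normalized volumetrically.
    """
    if sample_area_mm2 is None and sample_volume_mm3 is None:
        raise ValidationError("provide sample_area_mm2 and/or sample_volume_mm3")
    for denom in (sample_area_mm2, sample_volume_mm3):
        if denom is not None and denom <= 0:
            raise ValidationError("denominator must be positive")

    rows = []
    for roi in rois:
        for _, r in roi.composition.iterrows():
            rows.append({"sample_id": sample_id, "roi_id": roi.roi_id,
                         "area_um2": roi.area, "n_cells": roi.n_cells,
                         "center_x": roi.center[0], "center_y": roi.center[1],
                         "label": r["label"], "count": r["count"],
                         "proportion": r["proportion"]})
    composition = pd.DataFrame(
        rows, columns=["sample_id", "roi_id", "area_um2", "n_cells",
                       "center_x", "center_y", "label", "count", "proportion"])
    out = {"sample_id": sample_id, "n_rois": len(rois), "composition": composition}
    if sample_area_mm2 is not None:
        out["roi_density_per_mm2"] = len(rois) / sample_area_mm2
    if sample_volume_mm3 is not None:
        out["roi_density_per_mm3"] = len(rois) / sample_volume_mm3
    return out


def rois_to_table(rois: list[AlphaROI], labels: list[str]) -> pd.DataFrame:
    """One row per ROI: id, area, n_cells, centroid, per-label proportions."""
    rows = []
    for roi in rois:
        props = dict(zip(roi.composition["label"], roi.composition["proportion"]))
        rows.append({"roi_id": roi.roi_id, "area_um2": roi.area,
                     "n_cells": roi.n_cells,
                     "center_x": roi.center[0], "center_y": roi.center[1],
                     **{f"prop_{lab}": props.get(lab, 0.0) for lab in labels}})
    return pd.DataFrame(rows)
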