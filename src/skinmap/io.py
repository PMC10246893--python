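"""Tabular input/output and the core data containers.

The pipeline consumes three plain-text artifacts: a per-cell statistics
table (one row per segmented CD45+ cell, with coordinates, morphology and
per-channel mean fluorescence intensity), an attribution matrix (binary
marker signatures, one column per cell-type variant) and an epidermis
contour (x/y/z vertex list sampled from the structural surface).  All of
them are comma-separated UTF-8 text with a header row; a ``channel_map``
argument absorbs vendor-specific column naming so that exports from any
segmentation tool can be ingested without re-implementing its format.

Units are fixed throughout the package: coordinates in micrometres, areas
in square micrometres, volumes in cubic micrometres, MFI unitless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Non-channel columns of a cell table, in canonical order.
CELL_COLUMNS = ["cell_id", "x", "y", "z", "volume", "sphericity", "area"]


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Raised when a structurally well-formed input violates an invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CellTable:
    """Per-cell segmentation statistics for one sample.

    Parameters
    ----------
    sample_id : str
        Free-text sample identifier.
    cells : pandas.DataFrame
        One row per cell with the columns of :data:`CELL_COLUMNS` followed
        by one MFI column per channel.
    channels : list of str
        Names of the MFI columns, in panel order.
    """

    sample_id: str
    cells: pd.DataFrame
    channels: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise FormatError(f"cell table missing required column(s): {missing}")
        missing = [c for c in self.channels if c not in self.cells.columns]
        if missing:
            raise FormatError(f"cell table missing channel column(s): {missing}")
        if self.cells["cell_id"].duplicated().any():
            dupes = self.cells.loc[self.cells["cell_id"].duplicated(), "cell_id"]
            raise ValidationError(f"duplicate cell_id values: {sorted(set(dupes))[:5]}")
        mfi = self.cells[self.channels].to_numpy(dtype=float)
        if not np.isfinite(mfi).all() or (mfi < 0).any():
            raise ValidationError("MFI values must be finite and non-negative")
        coords = self.cells[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValidationError("cell coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def mfi_matrix(self, markers: Sequence[str] | None = None) -> np.ndarray:
        """Return the (n_cells, n_markers) MFI array for ``markers``."""
        markers = list(markers) if markers is not None else self.channels
        absent = [m for m in markers if m not in self.channels]
        if absent:
            raise ValidationError(f"channels not present in table: {absent}")
        return self.cells[markers].to_numpy(dtype=float)

    def positions(self, dims: str = "xy") -> np.ndarray:
        return self.cells[list(dims)].to_numpy(dtype=float)


@dataclass
class AttributionMatrix:
    """Binary marker-signature columns mapped to cell-type labels.

    A label may own several columns (a population that *can* express a
    marker is encoded as two columns, one with the entry set to 1 and one
    with it set to 0); column identifiers disambiguate them with a
    ``label#k`` suffix.
    """

    panel_name: str
    markers: list[str]
    values: pd.DataFrame            # markers x column_ids, entries in {0, 1}
    column_labels: dict[str, str]   # column_id -> label

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise FormatError("attribution matrix entries must be 0 or 1")
        if (vals.sum(axis=0) == 0).any():
            empty = [c for c in self.values.columns if self.values[c].sum() == 0]
            raise ValidationError(f"empty signature column(s): {empty}")
        if list(self.values.index) != self.markers:
            raise ValidationError("matrix row index must equal the marker list")

    @property
    def labels(self) -> list[str]:
        """Distinct cell-type labels, in column order."""
        seen: dict[str, None] = {}
        for cid in self.values.columns:
            seen.setdefault(self.column_labels[cid], None)
        return list(seen)

    def signature(self, column_id: str) -> set[str]:
        col = self.values[column_id]
        return {m for m in self.markers if col[m] == 1}


@dataclass
class EpidermisContour:
    """Ordered (x, y, z) vertices sampled from the epidermal surface."""

    vertices: np.ndarray  # (n, 3) in micrometres

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("contour vertices must be an (n, 3) array")
        if len(self.vertices) < 3:
            raise ValidationError("contour needs at least 3 vertices")
        if not np.isfinite(self.vertices).all():
            raise ValidationError("contour coordinates must be finite")


@dataclass
class RunConfig:
    """Run-level parameters of the pipeline.

    ``alpha_roi`` and ``alpha_epidermis`` are the α-shape parameters (in
    1/μm; a Delaunay simplex is kept when its circumradius is at most
    1/α), ``min_roi_cells`` the minimum cluster membership.
    """

    alpha_roi: float = 0.1
    alpha_epidermis: float = 0.4
    min_roi_cells: int = 15
    kde_grid_points: int = 512
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alpha_roi < 0 or self.alpha_epidermis < 0:
            raise ValidationError("alpha parameters must be >= 0")
        if self.min_roi_cells < 1:
            raise ValidationError("min_roi_cells must be >= 1")


@dataclass
class PanelValidationReport:
    """Result of cross-checking a matrix against a cell table."""

    missing_in_table: list[str] = field(default_factory=list)
    unused_in_matrix: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        """True when every matrix marker is measured in the table."""
        return not self.missing_in_table


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cell_table(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> CellTable:
    """Read a per-cell statistics CSV.

    Rows carrying a non-finite or negative MFI, or a non-finite
    coordinate, are rejected with a logged count rather than aborting the
    run — real exports contain boundary artifacts.

    Parameters
    ----------
    path : path-like
        CSV with the columns of :data:`CELL_COLUMNS` plus one column per
        channel (possibly under vendor names).
    channel_map : mapping, optional
        Raw column name -> canonical channel name.  Mapped columns are
        renamed before validation; unmapped extra columns are treated as
        channels as-is.
    sample_id : str, optional
        Defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if channel_map:
        df = df.rename(columns=dict(channel_map))
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    channels = [c for c in df.columns if c not in CELL_COLUMNS]
    if df["cell_id"].duplicated().any():
        raise ValidationError(f"{path.name}: duplicate cell_id values")

    numeric = df[CELL_COLUMNS[1:] + channels].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy()).all(axis=1)
    bad |= (numeric[channels].to_numpy() < 0).any(axis=1)
    if bad.any():
        logger.warning("%s: rejected %d row(s) with non-finite or negative values",
                       path.name, int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    df[CELL_COLUMNS[1:] + channels] = df[CELL_COLUMNS[1:] + channels].astype(float)
    df["cell_id"] = df["cell_id"].astype(int)
    return CellTable(sample_id or path.stem, df[CELL_COLUMNS + channels], channels)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    table.cells.to_csv(path, index=False)


def read_attribution_matrix(path: str | Path, panel_name: str | None = None) -> AttributionMatrix:
    """Read an attribution matrix (markers as rows, variants as columns).

    The first column holds marker names; remaining headers are column
    identifiers, either a plain label or ``label#k`` for the k-th variant
    of a label that can optionally express a marker.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.isna().to_numpy().any():
        raise FormatError(f"{path.name}: missing entries in attribution matrix")
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().to_numpy().any() or not np.isin(vals.to_numpy(), (0.0, 1.0)).all():
        raise FormatError(f"{path.name}: attribution matrix entries must be 0 or 1")
    column_labels = {cid: cid.split("#")[0] for cid in vals.columns}
    return AttributionMatrix(
        panel_name=panel_name or path.stem,
        markers=list(vals.index),
        values=vals.astype(float),
        column_labels=column_labels,
    )


def write_attribution_matrix(matrix: AttributionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "marker"
    out.to_csv(path)


def read_epidermis_contour(path: str | Path) -> EpidermisContour:
    """Read an epidermis contour CSV with columns x, y, z (micrometres)."""
    df = pd.read_csv(path)
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if len(cols) != 3:
        raise FormatError(f"{Path(path).name}: contour file needs x, y, z columns")
    return EpidermisContour(df[["x", "y", "z"]].to_numpy(dtype=float))


def write_epidermis_contour(contour: EpidermisContour, path: str | Path) -> None:
    pd.DataFrame(contour.vertices, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_run_config(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` configuration file."""
    kwargs: dict[str, float | int] = {}
    casts = {"alpha_roi": float, "alpha_epidermis": float,
             "min_roi_cells": int, "kde_grid_points": int, "seed": int}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"malformed config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in casts:
            raise FormatError(f"unknown config key: {key}")
        kwargs[key] = casts[key](value)
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# packaged panels
# ---------------------------------------------------------------------------

def load_default_matrix(panel: str) -> AttributionMatrix:
    """Load a packaged attribution matrix, ``"lymphoid"`` or ``"myeloid"``.

    The lymphoid panel enumerates 9 labels (B, NK, CD4/CD8 T split by
    CD57 level, γδ T with an optional-CD4 second column, dn and dp T) and
    the myeloid panel 10 (mast cells, neutrophils, eosinophils, basophils
    and the three dendritic-cell lineages split by HLA-DR level), 19
    immune subsets in total.
    """
    if panel not in ("lymphoid", "myeloid"):
        raise ValueError(f"unknown panel {panel!r}; expected 'lymphoid' or 'myeloid'")
    ref = resources.files("skinmap.data").joinpath(f"{panel}_matrix.csv")
    with resources.as_file(ref) as p:
        return read_attribution_matrix(p, panel_name=panel)


def validate_panel(table: CellTable, matrix: AttributionMatrix) -> PanelValidationReport:
    """Cross-check matrix markers against the channels measured in a table.

    Report-only: markers required by the matrix but absent from the table
    block a run (``report.ok`` is False); extra table channels (nuclear
    stains etc.) are merely listed as unused.
    """
    report = PanelValidationReport(
        missing_in_table=[m for m in matrix.markers if m not in table.channels],
        unused_in_matrix=[c for c in table.channels if c not in matrix.markers],
    )
    if report.missing_in_table:
        logger.warning("panel %s: markers missing from table: %s",
                       matrix.panel_name, report.missing_in_table)
    return report
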