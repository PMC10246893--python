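"""Activation-status detection by density-curve thresholding.

Activation markers (CD57 for T cells in the lymphoid panel, HLA-DR for
the dendritic-cell lineages in the myeloid panel) are informative rather
than discriminant: a population is split into a "low" and a "high"
fraction at a data-driven cutoff.  The cutoff is the MFI at the first
peak of the marker's kernel density estimate within the population,
scanning from low MFI — every cell strictly above it counts as positive.
A population-level z-score of the marker completes the readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribution import AnnotationResult
from .io import CellTable, ValidationError

logger = logging.getLogger(__name__)

#: (base population label, activation marker) pairs split by default.
DEFAULT_TARGETS: list[tuple[str, str]] = [
    ("CD4 T", "CD57"),
    ("CD8 T", "CD57"),
    ("dDC", "HLA-DR"),
    ("LC", "HLA-DR"),
    ("CD207+ dDC", "HLA-DR"),
]

MIN_POPULATION = 10  # below this a density curve is not meaningful

#: interior KDE maxima below this fraction of the global maximum are
#: treated as tail noise, not peaks
PEAK_RELATIVE_HEIGHT = 0.05


@dataclass
class ActivationConfig:
    targets: list[tuple[str, str]] = field(default_factory=lambda: list(DEFAULT_TARGETS))
    grid_points: int = 512

    def __post_init__(self) -> None:
        if self.grid_points < 64:
            raise ValidationError("grid_points must be >= 64")


def _silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    sd = values.std()
    q25, q75 = np.percentile(values, [25, 75])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * len(values) ** (-1 / 5)


def _kde_on_grid(values: np.ndarray, grid_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE evaluated on an even grid spanning [min, max]."""
    grid = np.linspace(values.min(), values.max(), grid_points)
    h = _silverman_bandwidth(values)
    if h <= 0:
        raise ValidationError("zero spread: density curve undefined")
    # direct evaluation; population sizes here are small enough for the
    # dense (grid x n) kernel matrix
    z = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (len(values) * h * np.sqrt(2 * np.pi))
    return grid, density


def activation_threshold(values: np.ndarray, grid_points: int = 512) -> float:
    """MFI at the first peak of the density curve of ``values``.

    The kernel density estimate (Gaussian kernel, Silverman bandwidth) is
    evaluated on ``grid_points`` evenly spaced points spanning the data
    range; the threshold is the grid location of the first strict local
    maximum.  A monotone curve has its "first peak" at the global
    maximum, i.e. the first grid point for a decreasing curve.

    Raises when fewer than 10 values or zero spread — a population too
    small or too degenerate to threshold.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValidationError("need at least 10 values to place a threshold")
    if values.max() == values.min():
        raise ValidationError("zero spread: threshold undefined")
    grid, density = _kde_on_grid(values, grid_points)
    peaks = _density_peaks(density)
    k = peaks[0] if len(peaks) else int(np.argmax(density))
    return float(grid[k])


def _density_peaks(density: np.ndarray) -> np.ndarray:
    """Indices of interior strict local maxima, tail noise excluded.

    A wiggle in a sparsely populated tail is a strict local maximum too;
    requiring :data:`PEAK_RELATIVE_HEIGHT` of the global maximum keeps
    only genuine modes.
    """
    interior = np.nonzero((density[1:-1] > density[:-2])
                          & (density[1:-1] > density[2:]))[0] + 1
    return interior[density[interior] >= PEAK_RELATIVE_HEIGHT * density.max()]


def split_activation(
    annotation: AnnotationResult,
    table: CellTable,
    config: ActivationConfig | None = None,
) -> tuple[AnnotationResult, pd.DataFrame]:
    """Split target populations into marker-low / marker-high variants.

    For each configured (population, marker) target, all cells whose
    label belongs to the population (the base label itself or an already
    suffixed variant of it) are pooled, the first-peak threshold of the
    marker is computed within the pool, and each cell is relabelled
    ``"<base> <marker>high"`` if its MFI is strictly above the threshold,
    ``"<base> <marker>low"`` otherwise.  Non-target populations are
    untouched.  Populations below :data:`MIN_POPULATION` are left unsplit
    with a logged warning.

    Returns the relabelled annotation and a threshold report with one row
    per target (population, marker, threshold, n, bandwidth).
    """
    config = config or ActivationConfig()
    cells = annotation.cells.copy()
    merged = cells.merge(table.cells[["cell_id"] + table.channels], on="cell_id")
    if len(merged) != len(cells):
        raise ValidationError("annotation and table cell_ids do not align")

    vocab = list(annotation.labels)
    report_rows = []
    for base, marker in config.targets:
        member = cells["label"].map(
            lambda lab: lab == base or str(lab).startswith(base + " "))
        n = int(member.sum())
        if n == 0:
            continue  # population not in this sample/panel
        if marker not in table.channels:
            raise ValidationError(f"activation marker {marker} not in table channels")
        values = merged.loc[member, marker].to_numpy(dtype=float)
        if n < MIN_POPULATION or values.max() == values.min():
            logger.warning("population %r too small/degenerate to split (n=%d)", base, n)
            continue
        thr = activation_threshold(values, config.grid_points)
        lo, hi = f"{base} {marker}low", f"{base} {marker}high"
        cells.loc[member, "label"] = np.where(values > thr, hi, lo)
        report_rows.append({"population": base, "marker": marker, "threshold": thr,
                            "n": n, "bandwidth": _silverman_bandwidth(values)})
        for lab in (lo, hi):
            if lab not in vocab:
                vocab.append(lab)

    # drop vocabulary entries that were dissolved into low/high variants
    still_used = set(cells["label"])
    vocab = [lab for lab in vocab if lab in still_used
             or not any(lab == b or lab.startswith(b + " ")
                        for b, _ in config.targets)]
    report = pd.DataFrame(report_rows,
                          columns=["population", "marker", "threshold", "n", "bandwidth"])
    return AnnotationResult(cells, labels=vocab), report


def mfi_zscore(values: np.ndarray) -> np.ndarray:
    """Standardize MFI values to zero mean and unit SD.

    The SD uses the n-1 divisor, matching the ``scale()`` convention of
    the usual statistics environments so that e.g. {1, 2, 3} maps to
    {-1, 0, 1}.  Raises on fewer than 2 values or zero spread.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values for a z-score")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero standard deviation: z-score undefined")
    return (values - values.mean()) / sd
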