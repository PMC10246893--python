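"""Cell-type annotation by rank correlation against adapted signatures.

The annotation engine scales a binary attribution matrix to the sample at
hand (every 1-entry becomes the channel's maximum observed MFI, the
"dynamic adaptation" step that makes signatures comparable across
acquisitions with different laser/gain settings), then scores every cell
against every signature column with Spearman's rank correlation and
assigns the label of the best-scoring column.  Cells whose best score is
shared by columns of *different* labels — or whose MFI vector is constant,
so that ranks are undefined — fall into the conservative sink label
``"Other"``.

A rule-based histo-cytometry gating oracle (the flow-cytometry-style
hierarchy used for validation) and the density-regression concordance
measure complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AttributionMatrix, CellTable, ValidationError

logger = logging.getLogger(__name__)

OTHER_LABEL = "Other"

#: Significant digits used when testing correlation scores for equality;
#: the assignment rule speaks of "multiple highest" scores without a
#: tolerance, so ties are detected after rounding to this precision.
TIE_SIGNIFICANT_DIGITS = 12


@dataclass
class AdaptedMatrix:
    """An attribution matrix rescaled to one sample.

    ``values[m, c]`` is 0 where the source matrix had 0 and the sample's
    maximum MFI of marker ``m`` where it had 1.
    """

    markers: list[str]
    values: pd.DataFrame
    column_labels: dict[str, str]

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid in self.values.columns:
            seen.setdefault(self.column_labels[cid], None)
        return list(seen)


@dataclass
class AnnotationResult:
    """Per-cell labels with correlation diagnostics.

    ``cells`` has columns ``cell_id, label, rho_best, rho_runner_up,
    tied``; correlation columns are NaN for results produced by gating.
    """

    cells: pd.DataFrame
    labels: list[str]  # label vocabulary of the method (without "Other")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def label_counts(self, include_other: bool = True) -> pd.Series:
        """Cell count per label, including zero-count labels."""
        vocab = self.labels + ([OTHER_LABEL] if include_other else [])
        counts = self.cells["label"].value_counts()
        return counts.reindex(vocab, fill_value=0).astype(int)


def adapt_matrix(matrix: AttributionMatrix, table: CellTable) -> AdaptedMatrix:
    """Rescale a binary matrix to a sample's per-channel maximum MFI.

    Raises on an empty table; a marker whose maximum MFI is 0 degrades
    every column using it (the column degenerates) and is logged.
    """
    if table.n_cells == 0:
        raise ValidationError("cannot adapt a matrix to an empty table")
    absent = [m for m in matrix.markers if m not in table.channels]
    if absent:
        raise ValidationError(f"matrix markers not measured in table: {absent}")
    maxima = table.cells[matrix.markers].max(axis=0)
    for marker, mx in maxima.items():
        if mx == 0:
            logger.warning("marker %s has maximum MFI 0; its signatures degenerate", marker)
    adapted = matrix.values.mul(maxima, axis=0)
    return AdaptedMatrix(list(matrix.markers), adapted, dict(matrix.column_labels))


def spearman_rho(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman's rank correlation with average ranks for ties.

    Returns NaN (the "undefined" flag) when either vector is constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValidationError("need at least 2 observations")
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    sa, sb = ra.std(), rb.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.dot(ra - ra.mean(), rb - rb.mean()) / (a.size * sa * sb))


def _rank_zscores(values: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centred and scaled; NaN rows where constant."""
    ranks = stats.rankdata(values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, ranks / sd, np.nan)


def annotate_cells(table: CellTable, adapted: AdaptedMatrix) -> AnnotationResult:
    """Assign each cell the label of its best-correlated signature column.

    Correlation is computed over the matrix's marker set only; extra
    channels in the table (nuclear stains etc.) are ignored.  Columns
    sharing a label compete as variants of that label: a tie between them
    is not a tie for assignment, whereas an exact tie (after rounding to
    :data:`TIE_SIGNIFICANT_DIGITS` significant digits) across *different*
    labels sends the cell to ``"Other"``, as does an all-constant MFI
    vector, for which rank correlation is undefined.
    """
    markers = adapted.markers
    X = table.mfi_matrix(markers)
    C = adapted.values.to_numpy(dtype=float).T  # columns x markers
    col_ids = list(adapted.values.columns)
    col_labels = np.array([adapted.column_labels[c] for c in col_ids])

    zx = _rank_zscores(X)
    zc = _rank_zscores(C)
    rho = zx @ zc.T / len(markers)  # NaN rows propagate

    # round to a fixed significant-digit budget so that "equal" is well defined
    with np.errstate(invalid="ignore"):
        mag = np.floor(np.log10(np.abs(rho), where=np.abs(rho) > 0,
                                out=np.zeros_like(rho)))
    decimals = TIE_SIGNIFICANT_DIGITS - 1 - mag
    rho_r = np.round(rho * 10.0 ** decimals) / 10.0 ** decimals

    n = table.n_cells
    labels_out = np.full(n, OTHER_LABEL, dtype=object)
    best = np.full(n, np.nan)
    runner = np.full(n, np.nan)
    tied = np.zeros(n, dtype=bool)

    valid = ~np.isnan(rho_r).all(axis=1)
    for i in np.nonzero(valid)[0]:
        row = rho_r[i]
        b = np.nanmax(row)
        winners = {lab for lab, r in zip(col_labels, row) if r == b}
        best[i] = b
        others = row[col_labels != next(iter(winners))] if len(winners) == 1 else row
        if len(winners) == 1:
            labels_out[i] = next(iter(winners))
            if others.size and not np.isnan(others).all():
                runner[i] = np.nanmax(others)
        else:
            tied[i] = True
            runner[i] = b

    cells = pd.DataFrame({
        "cell_id": table.cells["cell_id"].to_numpy(),
        "label": labels_out,
        "rho_best": best,
        "rho_runner_up": runner,
        "tied": tied,
    })
    return AnnotationResult(cells, labels=adapted.labels)


# ---------------------------------------------------------------------------
# histo-cytometry gating oracle
# ---------------------------------------------------------------------------

_REQUIREMENT_VALUES = {"+", "-", "low", "high", "."}


@dataclass
class GatingRuleSet:
    """Ordered flow-cytometry-style gates over per-marker cutoffs.

    Each rule maps markers to a requirement: ``+`` (above cutoff), ``-``
    (at or below), ``low``/``high`` (level split at the same cutoff,
    suffixing an otherwise positive population) or ``.`` (ignored).
    Rules are evaluated in order and the first match wins, mirroring a
    hierarchical manual gating tree.
    """

    rules: list[tuple[str, dict[str, str]]]
    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        for label, req in self.rules:
            bad = set(req.values()) - _REQUIREMENT_VALUES
            if bad:
                raise ValidationError(f"rule {label!r}: invalid requirement(s) {bad}")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.rules]

    @property
    def markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, req in self.rules:
            for m, r in req.items():
                if r != ".":
                    seen.setdefault(m, None)
        return list(seen)


def load_default_gates(panel: str, thresholds: Mapping[str, float]) -> GatingRuleSet:
    """Load the packaged gating hierarchy for a panel with given cutoffs."""
    if panel not in ("lymphoid", "myeloid"):
        raise ValueError(f"unknown panel {panel!r}")
    ref = resources.files("skinmap.data").joinpath(f"{panel}_gates.csv")
    with resources.as_file(ref) as p:
        return read_gating_rules(p, thresholds)


def read_gating_rules(path: str | Path, thresholds: Mapping[str, float]) -> GatingRuleSet:
    df = pd.read_csv(path, dtype=str).fillna(".")
    markers = [c for c in df.columns if c != "label"]
    rules = [(row["label"], {m: row[m] for m in markers if row[m] != "."})
             for _, row in df.iterrows()]
    return GatingRuleSet(rules, dict(thresholds))


def derive_gate_thresholds(
    table: CellTable,
    markers: Sequence[str],
    method: str = "valley",
    grid_points: int = 512,
) -> dict[str, float]:
    """Derive per-marker positivity cutoffs from the pooled MFI density.

    ``method="first_peak"`` applies the activation rule (cutoff at the
    first mode of the kernel density estimate); ``method="valley"`` puts
    the cutoff at the density minimum between the first two modes when
    the marker is bimodal, falling back to the first peak otherwise.
    Automatic derivation presumes a visible negative/positive separation;
    for markers without one (e.g. the pan-immune segmentation channel,
    positive on every cell) supply cutoffs explicitly instead.
    """
    from .activation import _density_peaks, _kde_on_grid  # avoid a cycle

    if method not in ("valley", "first_peak"):
        raise ValueError(f"unknown threshold method {method!r}")
    thresholds: dict[str, float] = {}
    for m in markers:
        values = table.cells[m].to_numpy(dtype=float)
        grid, density = _kde_on_grid(values, grid_points)
        peaks = _density_peaks(density)
        if method == "valley" and len(peaks) >= 2:
            lo, hi = peaks[0], peaks[1]
            thresholds[m] = float(grid[lo + np.argmin(density[lo:hi + 1])])
        else:
            k = peaks[0] if len(peaks) else int(np.argmax(density))
            thresholds[m] = float(grid[k])
    return thresholds


def gate_cells(table: CellTable, rules: GatingRuleSet) -> AnnotationResult:
    """Apply the gating hierarchy; cells failing every rule become "Other".

    Deterministic and threshold-driven; no correlation scores are set.
    """
    missing = [m for m in rules.markers if m not in table.channels]
    if missing:
        raise ValidationError(f"gating rules use unmeasured channels: {missing}")
    missing = [m for m in rules.markers if m not in rules.thresholds]
    if missing:
        raise ValidationError(f"no threshold supplied for marker(s): {missing}")

    X = table.mfi_matrix(rules.markers)
    t = np.array([rules.thresholds[m] for m in rules.markers])
    above = X > t  # "+" and "high" both mean strictly above the cutoff
    idx = {m: j for j, m in enumerate(rules.markers)}

    labels_out = np.full(table.n_cells, OTHER_LABEL, dtype=object)
    unassigned = np.ones(table.n_cells, dtype=bool)
    for label, req in rules.rules:
        mask = unassigned.copy()
        for m, r in req.items():
            if r == ".":
                continue
            want_above = r in ("+", "high")
            mask &= above[:, idx[m]] if want_above else ~above[:, idx[m]]
        labels_out[mask] = label
        unassigned &= ~mask

    cells = pd.DataFrame({
        "cell_id": table.cells["cell_id"].to_numpy(),
        "label": labels_out,
        "rho_best": np.nan,
        "rho_runner_up": np.nan,
        "tied": False,
    })
    # preserve first occurrence order of rule labels as the vocabulary
    vocab: dict[str, None] = {}
    for label, _ in rules.rules:
        vocab.setdefault(label, None)
    return AnnotationResult(cells, labels=list(vocab))


# ---------------------------------------------------------------------------
# concordance between two annotation routes
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    """Least-squares regression between two sets of per-label densities."""

    r: float
    slope: float
    intercept: float
    densities: pd.DataFrame  # label, density_a, density_b


def compare_annotations(
    a: AnnotationResult,
    b: AnnotationResult,
    labels: Sequence[str],
    roi_volume_mm3: float,
) -> ConcordanceResult:
    """Regress per-label cell densities of method ``b`` on method ``a``.

    Both results must stem from the same cell table (checked via the cell
    count).  Densities share one denominator, the imaged-box volume, so
    the regression is invariant to its value.  The returned ``r`` is the
    (Pearson) regression coefficient of the least-squares fit across
    labels — the quantity whose value between 0.75 and 1 certifies
    agreement of the two attribution routes.
    """
    if a.n_cells != b.n_cells:
        raise ValidationError("annotations compare different cell sets")
    if roi_volume_mm3 <= 0:
        raise ValidationError("roi_volume_mm3 must be positive")
    labels = list(labels)
    ca = a.label_counts().reindex(labels, fill_value=0)
    cb = b.label_counts().reindex(labels, fill_value=0)
    if (ca > 0).sum() < 3 or (cb > 0).sum() < 3:
        raise ValidationError("regression ill-posed: fewer than 3 labels with cells")
    da, db = ca / roi_volume_mm3, cb / roi_volume_mm3
    fit = stats.linregress(da.to_numpy(), db.to_numpy())
    table = pd.DataFrame({"label": labels,
                          "density_a": da.to_numpy(),
                          "density_b": db.to_numpy()})
    return ConcordanceResult(float(fit.rvalue), float(fit.slope),
                             float(fit.intercept), table)
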