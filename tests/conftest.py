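import numpy as np
import pandas as pd
import pytest

import skinmap as sm

SUITE_SEED = 123


@pytest.fixture(scope="session")
def suite():
    """The packaged benchmark fixture set, generated once per run."""
    return sm.generate_benchmark_suite(SUITE_SEED)


@pytest.fixture(scope="session")
def lymphoid_matrix():
    return sm.load_default_matrix("lymphoid")


@pytest.fixture(scope="session")
def myeloid_matrix():
    return sm.load_default_matrix("myeloid")


def annotation_from_truth(sample) -> sm.AnnotationResult:
    """Wrap a sample's ground-truth labels as an AnnotationResult."""
    cells = pd.DataFrame({
        "cell_id": sample.table.cells["cell_id"].to_numpy(),
        "label": sample.truth.to_numpy(),
        "rho_best": 1.0,
        "rho_runner_up": 0.0,
        "tied": False,
    })
    return sm.AnnotationResult(cells, labels=sorted(set(sample.truth)))


def small_cell_table(mfi: dict[str, list[float]], xy: np.ndarray | None = None,
                     sample_id: str = "toy") -> sm.CellTable:
    """Build a minimal in-memory cell table from per-channel MFI lists."""
    channels = list(mfi)
    n = len(next(iter(mfi.values())))
    if xy is None:
        xy = np.column_stack([np.linspace(10, 90, n), np.full(n, 50.0)])
    cells = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "x": xy[:, 0], "y": xy[:, 1], "z": np.full(n, 10.0),
        "volume": np.full(n, 150.0),
        "sphericity": np.full(n, 0.8),
        "area": np.full(n, 120.0),
        **{c: np.asarray(v, dtype=float) for c, v in mfi.items()},
    })
    return sm.CellTable(sample_id, cells, channels)
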