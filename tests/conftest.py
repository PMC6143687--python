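import numpy as np
import pandas as pd
import pytest

from cytotraject.io_cytometry import (
    EventTable,
    MarkerPanel,
    make_annotations,
)
from cytotraject.synthetic_data import default_sim_config, simulate_cohort


def make_table(X, markers=None, patient="P01", timepoint=1.0,
               population="unassigned", state="arcsinh(5)"):
    X = np.asarray(X, dtype=float)
    markers = markers or [f"M{i + 1}" for i in range(X.shape[1])]
    return EventTable(X, MarkerPanel.from_markers(markers),
                      make_annotations(X.shape[0], patient, timepoint,
                                       population), state)


def pool_tables(tables, keys=None):
    """Concatenate sample tables (sorted key order) into one EventTable."""
    keys = keys if keys is not None else sorted(tables)
    first = tables[keys[0]]
    return EventTable(
        np.vstack([tables[k].intensities for k in keys]),
        first.panel,
        pd.concat([tables[k].annotations for k in keys], ignore_index=True),
        first.transform_state)


@pytest.fixture(scope="session")
def small_cohort():
    """One-patient default cohort, 400 cells/sample, with ground truth."""
    cfg = default_sim_config(n_patients=1, cells_per_sample=400, seed=7)
    tables, metas, truth = simulate_cohort(cfg)
    return cfg, tables, metas, truth


@pytest.fixture(scope="session")
def two_blobs():
    """Two well-separated 2-D Gaussian blobs with known membership."""
    rng = np.random.default_rng(42)
    a = rng.normal([0.0, 0.0], 0.5, size=(400, 2))
    b = rng.normal([8.0, 8.0], 0.5, size=(400, 2))
    coords = np.vstack([a, b])
    membership = np.array([0] * 400 + [1] * 400)
    return coords, membership
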