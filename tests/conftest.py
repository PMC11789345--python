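import numpy as np
import pandas as pd
import pytest

import fiberfa as ff

PANEL = ["Myh1", "Myh2", "Myh4", "Myh7", "Myh7b", "Myh11", "Myh3"]


@pytest.fixture(scope="session")
def default_counts():
    """One default synthetic dataset shared across read-only tests."""
    return ff.generate_fiber_counts(ff.SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_expr(default_counts):
    cm, truth = default_counts
    filtered, qc = ff.qc_filter(cm)
    expr = ff.normalize_log_rpm(filtered)
    kept = set(filtered.cells)
    truth_kept = truth.frame[truth.frame["cell"].isin(kept)].reset_index(drop=True)
    return expr, truth_kept


@pytest.fixture(scope="session")
def default_fit(default_expr):
    expr, truth = default_expr
    model = ff.FiberFactorModel(expr, panel=PANEL)
    return model.fit(seed=1), truth


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on defaults, shared across read-only tests."""
    return ff.run_pipeline(seed=3)


@pytest.fixture()
def toy_go():
    return {
        "Myh7": {"a", "b", "c", "d", "e", "f"},
        "Myh1": {"p", "q", "r"},
        "Myh7b": {"a", "b", "c", "d", "x", "y"},  # 4 of Myh7's 6
        "Actb": {"z1", "z2"},
    }


def make_counts(counts, cells=None, genes=None, condition=None):
    counts = np.asarray(counts)
    n, p = counts.shape
    return ff.CountMatrix(
        cells=cells or [f"c{i}" for i in range(n)],
        genes=genes or [f"g{j}" for j in range(p)],
        counts=counts,
        condition=condition,
    )
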