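import numpy as np
import pandas as pd
import pytest

from hemoconcord import (
    ClusterLabeling,
    CountMatrix,
    MarkerTable,
    NormMatrix,
    RegulonSet,
    StudyConfig,
    generate_study,
    lognormalize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_counts(rng):
    """50 cells x 100 genes of Poisson counts."""
    values = rng.poisson(1.0, size=(50, 100))
    return CountMatrix(
        values,
        [f"c{i}" for i in range(50)],
        [f"g{i}" for i in range(100)],
    )


@pytest.fixture
def tiny_labeling():
    labels = {f"c{i}": ("A" if i < 25 else "B") for i in range(50)}
    return ClusterLabeling(labels)


@pytest.fixture
def small_study():
    """Four equal subgroups, planted markers, enough cells for detection."""
    cfg = StudyConfig(
        n_cells=400,
        n_genes=300,
        proportions={s: 0.25 for s in ["A", "B", "C", "D"]},
        markers_per_subgroup=10,
        marker_log2fc=2.0,
        seed=7,
    )
    cm, gt = generate_study(cfg)
    return cm, gt


@pytest.fixture
def small_norm(small_study):
    cm, gt = small_study
    return lognormalize(cm), gt


def marker_table(rows):
    """Build a MarkerTable from (gene, subgroup, log2fc) triples."""
    df = pd.DataFrame(rows, columns=["gene", "subgroup", "log2fc"])
    df["p"] = 1e-6
    df["p_adj"] = 1e-4
    df["pct_in"] = 0.9
    df["pct_out"] = 0.1
    return MarkerTable(df)
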