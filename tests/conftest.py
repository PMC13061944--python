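import numpy as np
import pandas as pd
import pytest

from cytolag.io_qc import CountMatrix
from cytolag.simulate import SimConfig, simulate_cells


@pytest.fixture
def toy_counts():
    """4 genes x 3 cells, one mitochondrial gene."""
    values = np.array(
        [
            [5, 0, 2],
            [1, 3, 0],
            [0, 2, 0],
            [4, 5, 8],  # MT-CO1
        ]
    )
    return CountMatrix(values, ["ACTB", "IFNG", "TNF", "MT-CO1"], ["c1", "c2", "c3"], "rna")


@pytest.fixture
def toy_annotation():
    return pd.DataFrame(
        {
            "is_mito": [False, False, False, True],
            "category": ["other", "cytokine", "cytokine", "other"],
            "is_cytokine": [False, True, True, False],
            "paired_adt_id": [None, "IFNG-ADT", "TNF-ADT", None],
        },
        index=pd.Index(["ACTB", "IFNG", "TNF", "MT-CO1"], name="feature_id"),
    )


@pytest.fixture
def toy_meta():
    return pd.DataFrame(
        {
            "sample_id": ["S1", "S1", "S1"],
            "condition": ["stimulated", "unstimulated", "stimulated"],
            "cell_type": ["T", "T", "NK"],
        },
        index=pd.Index(["c1", "c2", "c3"], name="cell_id"),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset shared across tests (seed fixed)."""
    return simulate_cells(SimConfig(seed=20240901 % 2**31))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast dataset for pipeline-level tests."""
    return simulate_cells(SimConfig(n_cells=400, seed=7))
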