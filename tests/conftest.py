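import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hspcflow import qc, simdata


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimConfig(
        n_types=5,
        n_genes=400,
        markers_per_type=10,
        n_cells_per_donor=150,
        donors_per_condition={"young": 2, "elderly": 2},
        n_dynamic_genes=12,
        n_regulons=8,
        seed=42,
    )


@pytest.fixture(scope="session")
def reference_small(small_config):
    return simdata.generate_reference(small_config)


@pytest.fixture(scope="session")
def query_small(small_config, reference_small):
    _, truth = reference_small
    return simdata.generate_query(small_config, truth)


@pytest.fixture(scope="session")
def qc_fixture():
    """100-cell count matrix with known QC violations (3 high-mito, 2
    low-mito, 2 doublet-like) and thresholds under which 93 cells pass."""
    from hspcflow import evaluation

    return evaluation.build_qc_fixture(seed=10)
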