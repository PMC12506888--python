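import numpy as np
import pytest

import knowclust as kc


@pytest.fixture
def tiny_counts():
    """3 cells x 2 genes raw counts."""
    return kc.ExpressionMatrix(
        np.array([[1.0, 3.0], [0.0, 2.0], [4.0, 0.0]]),
        ["c1", "c2", "c3"], ["gA", "gB"],
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small 3-type dataset used by several integration tests."""
    spec = kc.SimulationSpec(
        n_types=3, cells_per_type=120, n_genes=800, markers_per_type=20, seed=7
    )
    return kc.simulate_counts(spec)


@pytest.fixture(scope="session")
def small_split(small_sim):
    return kc.split_reference_query(small_sim, query_fraction=0.5, seed=7)


@pytest.fixture(scope="session")
def small_kb(small_split):
    ref, _ = small_split
    return kc.build_knowledgebase(ref.rna, ref.labels, method="stability", n_top=50)


@pytest.fixture(scope="session")
def small_config():
    return kc.RunConfig(seed=7, min_cells=15, epochs=20)


@pytest.fixture(scope="session")
def small_result(small_split, small_kb, small_config):
    _, query = small_split
    return kc.cluster_query(query.rna, small_kb, config=small_config)
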