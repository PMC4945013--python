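import numpy as np
import pandas as pd
import pytest

from comorbevol import (
    GeneStatsTable,
    SimulationConfig,
    build_presence_matrix,
    gen_association_matrix,
    gen_gene_stats,
    partition_by_cluster,
)


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def planted(default_cfg):
    """Default planted-structure synthetic associations + truth."""
    return gen_association_matrix(default_cfg)


@pytest.fixture(scope="session")
def planted_matrix(planted):
    assoc, _ = planted
    return build_presence_matrix(assoc)


@pytest.fixture(scope="session")
def planted_partition(planted, planted_matrix):
    _, truth = planted
    return partition_by_cluster(planted_matrix, truth.focal, truth.cluster)


@pytest.fixture(scope="session")
def planted_stats(planted, default_cfg):
    _, truth = planted
    return gen_gene_stats(truth, default_cfg)


def stats_from_arrays(pn, ps, dnds=None, genes=None) -> GeneStatsTable:
    """Build a GeneStatsTable from plain arrays for oracle-style tests."""
    n = len(pn)
    genes = genes if genes is not None else [f"g{i}" for i in range(n)]
    data = {"pN": np.asarray(pn, float), "pS": np.asarray(ps, float)}
    if dnds is not None:
        data["dnds"] = np.asarray(dnds, float)
    return GeneStatsTable(
        frame=pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    )
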