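import numpy as np
import pytest

from ccckit import (
    MethodConfig,
    ScenarioConfig,
    add_consensus,
    generate_dataset,
    generate_resource,
    score_methods,
)
from ccckit.cluster_stats import ExpressionDataset


def make_dataset(counts, clusters, genes=None):
    """Build a small dataset from a genes x cells count array."""
    counts = np.asarray(counts)
    if genes is None:
        genes = [f"g{i}" for i in range(counts.shape[0])]
    cells = [f"c{i}" for i in range(counts.shape[1])]
    return ExpressionDataset.from_counts(counts, genes, cells, clusters)


@pytest.fixture(scope="session")
def default_scenario():
    """The default planted scenario: 20 clusters x 100 cells, 2000 genes."""
    cfg = ScenarioConfig(seed=1)
    dataset, truth = generate_dataset(cfg)
    resource = generate_resource(cfg, truth)
    return cfg, dataset, truth, resource


@pytest.fixture(scope="session")
def default_scored(default_scenario):
    cfg, dataset, truth, resource = default_scenario
    return score_methods(dataset, resource, "all", MethodConfig(seed=cfg.seed))


@pytest.fixture(scope="session")
def default_consensus(default_scored):
    return add_consensus(default_scored)


@pytest.fixture(scope="session")
def small_scenario():
    """A fast scenario for tests that re-score repeatedly."""
    cfg = ScenarioConfig(
        seed=7,
        n_genes=400,
        n_clusters=5,
        cells_per_cluster=40,
        n_planted_pairs=5,
        n_decoy_interactions=20,
        n_cytokines=2,
        signature_genes_per_cytokine=10,
        n_coloc_pairs=2,
    )
    dataset, truth = generate_dataset(cfg)
    resource = generate_resource(cfg, truth)
    return cfg, dataset, truth, resource
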