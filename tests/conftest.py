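import logging

import numpy as np
import pytest

import tumorevo.cna as cna
import tumorevo.segmentation as seg
import tumorevo.simulate as sim

logging.getLogger("tumorevo").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def scenario():
    """Default planted scenario run through the expression pipeline once."""
    config = sim.default_scenario(seed=0)
    matrix, truth = sim.simulate_expression(config)
    z, normalized = cna.prepare_smoothed_z(matrix)
    cycle = cna.score_cell_cycle(normalized, truth.g1s_genes, truth.g2m_genes)
    embedding = cna.pca_project(z, cycle["cycling"].to_numpy())
    graph = cna.build_knn_graph(embedding)
    partition = cna.detect_communities(graph, seed=0)
    return {
        "config": config,
        "matrix": matrix,
        "truth": truth,
        "z": z,
        "normalized": normalized,
        "cycle": cycle,
        "embedding": embedding,
        "graph": graph,
        "partition": partition,
    }


@pytest.fixture(scope="session")
def metacells(scenario):
    truth = scenario["truth"]
    baseline = np.flatnonzero((truth.cells["clone"] == "normal").to_numpy())
    return seg.make_metacells(
        scenario["matrix"], scenario["partition"].labels, baseline, seed=7
    )


@pytest.fixture(scope="session")
def profiles(metacells):
    return {
        c: seg.call_community_profile(metacells, c) for c in metacells.communities()
    }


@pytest.fixture(scope="session")
def small_matrix():
    """Tiny deterministic expression matrix for unit tests."""
    config = sim.ExpressionSimConfig(
        genes_per_chrom={"chr1": 40, "chr2": 40},
        clones=[sim.CloneSpec("cloneA", 30, [("chr1", "p", "loss")])],
        n_normal_cells=30,
        seed=42,
    )
    return sim.simulate_expression(config)
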