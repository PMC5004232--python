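import logging

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metadriver import CohortLabels, PlantedScenario, VariantRecord, generate_cohort

logging.getLogger("metadriver").setLevel(logging.ERROR)


@pytest.fixture
def small_labels():
    return CohortLabels(
        {"h1": "HRM", "h2": "HRM", "h3": "HRM", "l1": "LRM", "l2": "LRM", "l3": "LRM"}
    )


@pytest.fixture
def toy_variants():
    return [
        VariantRecord("h1", "GENE1", "p.A1T", "missense", "exon", 0.001),
        VariantRecord("h2", "GENE1", "p.A1T", "missense", "exon", 0.001),
        VariantRecord("h1", "GENE2", "p.R5Q", "nonsense", "splice_site", None),
        VariantRecord("l1", "GENE3", "p.G7D", "frameshift_indel", "exon", 0.05),
    ]


@pytest.fixture(scope="session")
def default_scenario():
    return PlantedScenario(seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_scenario):
    return generate_cohort(default_scenario)


@pytest.fixture
def chain_network():
    """m — p — f with Pearson weights 0.9 and 0.8."""
    g = nx.Graph()
    g.add_edge("m", "p", weight=0.9)
    g.add_edge("p", "f", weight=0.8)
    return g


def random_binary_matrix(rng, m, n, density=0.3):
    a = (rng.random((m, n)) < density).astype(int)
    a = a[:, a.sum(axis=0) > 0]
    return a


@pytest.fixture
def correlated_expression():
    """30 samples; g1 and g2 collinear, g3 independent noise."""
    rng = np.random.default_rng(5)
    base = rng.normal(10, 2, 30)
    return pd.DataFrame(
        {
            "g1": base,
            "g2": 2.0 * base + 1.0,
            "g3": rng.normal(10, 2, 30),
        }
    ).T.set_axis([f"s{i}" for i in range(30)], axis=1)
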