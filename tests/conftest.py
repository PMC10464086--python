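import dendropy
import numpy as np
import pandas as pd
import pytest

from sedstrat import GeneratorConfig, generate_dataset
from sedstrat.containers import CommunityMatrix


@pytest.fixture(scope="session")
def three_taxon_tree():
    """((A:1,B:1):1,C:2): patristic A-B = 2, A-C = B-C = 4."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture(scope="session")
def three_taxon_dist(three_taxon_tree):
    from sedstrat.trees import patristic_matrix

    return patristic_matrix(three_taxon_tree)


@pytest.fixture(scope="session")
def small_dataset():
    """Default study-design dataset at desk scale, shared across tests."""
    return generate_dataset(GeneratorConfig(n_taxa=150, seed=0))


def make_matrix(counts: dict, layers=None, seasons=None) -> CommunityMatrix:
    """Build a CommunityMatrix from a {sample: [counts]} dict."""
    df = pd.DataFrame(counts)
    df.index = [f"t{i}" for i in range(df.shape[0])]
    n = df.shape[1]
    meta = pd.DataFrame(
        {
            "layer": layers if layers is not None else np.arange(1, n + 1),
            "season": seasons if seasons is not None else ["S1"] * n,
        },
        index=df.columns,
    )
    return CommunityMatrix(df, meta)
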