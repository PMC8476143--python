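import numpy as np
import pandas as pd
import pytest

import intronevo as ie


@pytest.fixture
def balanced4():
    return ie.read_newick("((A:1,B:1)ab:1,(C:1,D:1)cd:1);")


@pytest.fixture
def five_leaf():
    return ie.read_newick("((A,B),(C,(D,E)));")


@pytest.fixture(scope="session")
def small_bundle():
    """One shared desk-scale synthetic bundle (8 leaves, 400 sites)."""
    return ie.simulate_bundle(seed=11, n_leaves=8, n_sites=400, n_genes=60)


def make_table(species, rows, meta=None):
    """Site table from a list of state strings like '10?1'."""
    states = np.array(
        [[{"0": 0, "1": 1, "?": 2}[ch] for ch in row] for row in rows],
        dtype=np.int8,
    )
    if meta is None:
        meta = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(len(rows))],
                "gene_id": ["g0"] * len(rows),
                "ordinal": np.arange(1, len(rows) + 1),
                "cds_offset": np.arange(1, len(rows) + 1) * 10,
            }
        )
    return ie.IntronSiteTable(species, states, meta)
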