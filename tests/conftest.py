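import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from gmeb.datasets import CommunityDataset, OtuTable, SampleMetadata, TaxonomyMap
from gmeb.simulate import ImpactParams, SimulationParams, simulate_dataset, simulate_impacted


def make_metadata(sample_ids, **overrides):
    n = len(sample_ids)
    base = {
        "latitude": np.linspace(25, 45, n),
        "longitude": np.linspace(90, 120, n),
        "well_depth": np.linspace(10, 80, n),
        "well_type": ["newly_constructed"] * n,
        "water_type": ["phreatic"] * n,
        "geo_zone": ["II"] * n,
    }
    base.update(overrides)
    return SampleMetadata(pd.DataFrame(base, index=sample_ids))


@pytest.fixture
def tiny_table():
    counts = np.array([[10, 5, 0, 1], [0, 8, 2, 0], [3, 3, 3, 3]])
    return OtuTable(counts, ["s1", "s2", "s3"], ["A", "B", "C", "D"])


@pytest.fixture
def tiny_dataset(tiny_table):
    tax = TaxonomyMap.from_lineage_strings({
        "A": "Bacteria;Phy1;c;o;f;GenX;sp1",
        "B": "Bacteria;Phy1;c;o;f;GenX;sp2",
        "C": "Bacteria;Phy2;c;o;f;GenY;sp3",
        "D": "Bacteria;Phy2",
    })
    tree = TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1.5,D:1.5):0.5):0.0;"))
    meta = make_metadata(["s1", "s2", "s3"])
    return CommunityDataset(tiny_table, tax, meta, tree)


@pytest.fixture(scope="session")
def baseline_sim():
    """Medium synthetic baseline survey shared by the slower tests."""
    return simulate_dataset(SimulationParams(n_sites=60, seed=21))


@pytest.fixture(scope="session")
def impacted_strong(baseline_sim):
    sim = simulate_impacted(baseline_sim, ImpactParams(0.5, 0.5, seed=22))
    return sim.dataset.subset_samples(sim.dataset.table.sample_ids[:30])
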