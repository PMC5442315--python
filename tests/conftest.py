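import pytest

from epistates.peak_pipeline import (
    ConsensusMarkSet,
    ReplicateRegionSet,
    concordance_filter,
    consensus_regions,
)
from epistates.synthetic_data import SimulationConfig, simulate


def build_consensus(ds, mark: str, timepoint: str) -> ConsensusMarkSet:
    """Filter-then-consensus for one mark/timepoint of a simulated dataset."""
    r1 = ds.replicates[(mark, timepoint, 1)]
    r2 = ds.replicates[(mark, timepoint, 2)]
    res = concordance_filter(r1, r2)
    return consensus_regions(
        ReplicateRegionSet(mark, timepoint, 1, res.rep1_kept),
        ReplicateRegionSet(mark, timepoint, 2, res.rep2_kept),
    )


@pytest.fixture(scope="session")
def dataset2000():
    """Default-condition simulation at n=2000, shared across tests."""
    return simulate(SimulationConfig(seed=11, n_genes=2000))


@pytest.fixture(scope="session")
def dataset_small():
    return simulate(SimulationConfig(seed=5, n_genes=300))
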