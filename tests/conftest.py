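import numpy as np
import pytest

from coexnet import ModulePartition, SyntheticSpec, simulate


@pytest.fixture(scope="session")
def sim_two_modules():
    """Two planted modules of 20 transcripts over a 10x3 tissue panel."""
    return simulate(
        SyntheticSpec(
            n_modules=2,
            transcripts_per_module=20,
            n_tissues=10,
            replicates_per_tissue=3,
            noise_sd=0.1,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def sim_benchmark():
    """The 10-modules-of-50 planted benchmark used for recovery checks."""
    return simulate(
        SyntheticSpec(
            n_modules=10,
            transcripts_per_module=50,
            n_tissues=10,
            replicates_per_tissue=3,
            noise_sd=0.2,
            background_fraction=0.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def sim_many_small():
    """Many small planted modules: the regime where modularity's
    resolution scale is coarser than the module size, so whole modules
    are representable as single communities."""
    return simulate(
        SyntheticSpec(
            n_modules=12,
            transcripts_per_module=6,
            n_tissues=12,
            replicates_per_tissue=3,
            noise_sd=0.1,
            seed=42,
        )
    )


@pytest.fixture()
def toy_partition():
    """Six transcripts in three two-member modules."""
    return ModulePartition(
        ["t1", "t2", "t3", "t4", "t5", "t6"],
        np.array([0, 0, 1, 1, 2, 2]),
        modularity=0.0,
        seed=1,
        weighting_mode="similarity",
    )
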