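import numpy as np
import pytest

from homeopipe import subassign, synthsim


@pytest.fixture(scope="session")
def small_config() -> synthsim.SimulationConfig:
    """Small but structurally complete study used across modules."""
    return synthsim.SimulationConfig.desk_scale(
        seed=11,
        n_pairs=80,
        n_unpaired_per_subgenome=8,
        reads_per_sample=5000,
        n_de_genes=16,
        n_coordinated_pairs=5,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return synthsim.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_indices(small_truth):
    return (
        subassign.build_index(small_truth.at, 21),
        subassign.build_index(small_truth.aa, 21),
    )


@pytest.fixture(scope="session")
def sample_assignments(small_truth, small_indices):
    """Assignments plus origin truth for acc1 replicate 1."""
    idx_at, idx_aa = small_indices
    fragments, origin = synthsim.simulate_reads(small_truth, "acc1", 1)
    assignments = subassign.assign_sample(fragments, idx_at, idx_aa)
    return fragments, origin, assignments


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
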