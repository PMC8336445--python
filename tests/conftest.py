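import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cenhor.align import consensus
from cenhor.monomers import MonomerGenParams, generate_monomers
from cenhor.sim import SimulationSpec, simulate_array


@pytest.fixture(scope="session")
def small_sim():
    """A 3-monomer, 60-unit synthetic array with its ground truth."""
    spec = SimulationSpec(n_monomers=3, n_units=60, seed=7)
    seq, truth = simulate_array(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def small_inference(small_sim):
    """Monomer inference run once on the small array (shared, read-only)."""
    _, seq, truth = small_sim
    init = consensus(truth.monomers).consensus
    monomers, blocks, log = generate_monomers(
        seq, init, MonomerGenParams(), seq_id="sim"
    )
    return seq, truth, monomers, blocks, log
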