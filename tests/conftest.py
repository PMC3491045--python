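import numpy as np
import pytest

from bindturnover import divergence, synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimulationConfig(
        genome_length=100_000, n_sites=60, n_genes=20, n_tes=5,
        depth=100_000, seed=1)


@pytest.fixture(scope="session")
def designed_truth(small_config):
    """60 sites: 30 shared, 15 mel-only, 15 other-only."""
    presence = np.zeros((60, 4), dtype=int)
    presence[:30] = (1, 1, 1, 1)
    presence[30:45] = (1, 0, 0, 0)
    presence[45:] = (0, 1, 1, 1)
    return synthetic.simulate_binding_history(small_config, presence=presence)


@pytest.fixture(scope="session")
def pair_reads(small_config, designed_truth):
    return synthetic.simulate_chip_reads(designed_truth, small_config,
                                         species=("mel", "sim"))


@pytest.fixture(scope="session")
def pair_run(small_config, designed_truth, pair_reads):
    """Full mel-vs-sim divergence analysis of the designed landscape."""
    maps, _ = synthetic.simulate_orthology(small_config, designed_truth)
    reads = pair_reads
    result = divergence.analyze_pair(
        [reads[("mel", "chip", r + 1)] for r in range(3)],
        [reads[("mel", "input", r + 1)] for r in range(3)],
        [reads[("sim", "chip", r + 1)] for r in range(3)],
        [reads[("sim", "input", r + 1)] for r in range(3)],
        small_config.genome_length, orthology_map=maps["sim"], seed=1)
    return result
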