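import numpy as np
import pytest

from ntve.simulate import SimulationConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_transcriptome():
    """40 single-isoform genes, 3.5-5 kb, one spike-in, no mito genes."""
    cfg = SimulationConfig(n_genes=40, length_range=(3500, 5000), mito_fraction=0.0, seed=4)
    seqs, ann = simulate_transcriptome(cfg)
    return cfg, seqs, ann
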